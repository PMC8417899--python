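"""The stimulus-association pipeline: epoch segmentation, augmentation,
dataset assembly, feature ranking, splitting, and pluggable classifiers.

This ties stimulus schedules to HRV: RR segments are cut per stimulus epoch,
optionally augmented (noise addition or overlapping windows), summarized as
HRV feature vectors or CWT scalograms, ranked by mutual information with the
stimulus class, split into train/test (optionally subject-aware to prevent
leakage), and classified with any backend exposing ``fit``/``predict``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import pywt

from .core import RrSeries
from .hrv import all_features
from .schedule import StimulusSchedule

__all__ = [
    "Segment",
    "Dataset",
    "Scalogram",
    "SplitPlan",
    "segment_epochs",
    "augment",
    "build_feature_dataset",
    "scalogram",
    "rank_features",
    "split_dataset",
    "fit_predict",
    "NearestCentroidBackend",
    "KnnBackend",
]


@dataclass(frozen=True)
class Segment:
    """One stimulus epoch's worth of RR signal with its class labels."""

    subject_id: str
    general_class: str
    subclass: str
    rr: RrSeries
    parent_id: str | None = None
    segment_id: str = ""


@dataclass(frozen=True)
class Dataset:
    """Feature matrix with aligned labels and subject ids.

    ``X`` rows correspond one-to-one to ``labels`` and ``subjects``.
    ``dropped_columns`` records features removed because they were flagged
    undefined in at least one segment (nothing is dropped silently).
    """

    X: pd.DataFrame
    labels: tuple[str, ...]
    subjects: tuple[str, ...]
    dropped_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.labels) == len(self.subjects)):
            raise ValueError("rows, labels and subject ids must align")
        if self.X.isna().any().any():
            raise ValueError("dataset contains missing values")

    def __len__(self) -> int:
        return len(self.X)

    def take(self, idx: Sequence[int]) -> "Dataset":
        idx = list(idx)
        return Dataset(
            self.X.iloc[idx].reset_index(drop=True),
            tuple(self.labels[i] for i in idx),
            tuple(self.subjects[i] for i in idx),
            self.dropped_columns,
        )


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitude (scales x time) with the scale-to-frequency map."""

    magnitude: np.ndarray
    frequencies_hz: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape[0] != len(self.scales):
            raise ValueError("scale count must match magnitude rows")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")


@dataclass(frozen=True)
class SplitPlan:
    """Train/test (and optional k-fold) index sets over a dataset."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    train_fraction: float
    group_aware: bool
    seed: int
    folds: tuple[tuple[int, ...], ...] = ()


def segment_epochs(
    rr: RrSeries,
    schedule: StimulusSchedule,
    min_duration_s: float = 10.0,
    subject_id: str = "S000",
) -> list[Segment]:
    """Cut one RR segment per stimulus epoch.

    An interval belongs to the epoch containing its anchor time (epochs are
    half-open). Epochs shorter than ``min_duration_s`` are dropped with a
    warning; an epoch extending past the record's last beat is an error.
    """
    record_end = rr.anchor_times_s[-1]
    segments: list[Segment] = []
    for k, epoch in enumerate(schedule):
        if epoch.end_s > record_end + 1e-9:
            raise ValueError(
                f"epoch [{epoch.onset_s}, {epoch.end_s}) extends past the "
                f"record end at {record_end:.2f} s"
            )
        if epoch.duration_s < min_duration_s:
            warnings.warn(
                f"epoch at {epoch.onset_s} s lasts {epoch.duration_s} s "
                f"(< {min_duration_s} s); dropped",
                stacklevel=2,
            )
            continue
        sel = (rr.anchor_times_s >= epoch.onset_s) & (rr.anchor_times_s < epoch.end_s)
        if not np.any(sel):
            warnings.warn(
                f"epoch at {epoch.onset_s} s contains no beats; dropped",
                stacklevel=2,
            )
            continue
        segments.append(
            Segment(
                subject_id=subject_id,
                general_class=epoch.general_class,
                subclass=epoch.subclass,
                rr=RrSeries(rr.intervals_ms[sel], rr.anchor_times_s[sel]),
                segment_id=f"{subject_id}/e{k:03d}",
            )
        )
    return segments


def _augment_noise(
    segments: list[Segment], k: int, sd_ms: float, rng: np.random.Generator
) -> list[Segment]:
    out = []
    for seg in segments:
        for j in range(k):
            noisy = seg.rr.intervals_ms + rng.normal(0.0, sd_ms, len(seg.rr))
            noisy = np.maximum(noisy, 1.0)
            out.append(
                replace(
                    seg,
                    rr=RrSeries(noisy, seg.rr.anchor_times_s),
                    parent_id=seg.segment_id,
                    segment_id=f"{seg.segment_id}/n{j}",
                )
            )
    return out


def _augment_windows(
    segments: list[Segment], window_s: float, overlap: float
) -> list[Segment]:
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    step = window_s * (1 - overlap)
    out = []
    for seg in segments:
        t = seg.rr.anchor_times_s
        t0 = t[0] - seg.rr.intervals_ms[0] / 1000.0
        total = t[-1] - t0
        if window_s > total:
            warnings.warn(
                f"window {window_s} s exceeds segment {seg.segment_id} "
                f"({total:.1f} s); passed through unchanged",
                stacklevel=3,
            )
            out.append(seg)
            continue
        n_win = int(np.floor((total - window_s) / step + 1e-9)) + 1
        for j in range(n_win):
            lo = t0 + j * step
            hi = lo + window_s
            sel = (t >= lo) & (t < hi + 1e-9)
            if not np.any(sel):
                continue
            out.append(
                replace(
                    seg,
                    rr=RrSeries(seg.rr.intervals_ms[sel], t[sel]),
                    parent_id=seg.segment_id,
                    segment_id=f"{seg.segment_id}/w{j}",
                )
            )
    return out


def augment(
    segments: list[Segment],
    method: str,
    *,
    k: int = 2,
    noise_sd_ms: float = 5.0,
    window_s: float = 10.0,
    overlap: float = 0.5,
    seed: int = 0,
) -> list[Segment]:
    """Data augmentation by noise addition or (overlapping) windowing.

    Every derived segment inherits its parent's labels and records the
    parent's id. ``noise_addition`` yields ``k`` jittered copies per
    segment; ``windowing`` slides a ``window_s`` window with fractional
    ``overlap`` (a window equal to the segment length reproduces it once).
    """
    if not segments:
        raise ValueError("no segments to augment")
    if method == "noise_addition":
        return _augment_noise(segments, k, noise_sd_ms, np.random.default_rng(seed))
    if method == "windowing":
        return _augment_windows(segments, window_s, overlap)
    raise ValueError(f"unknown augmentation method {method!r}")


def build_feature_dataset(
    segments: list[Segment],
    label_level: str = "subclass",
    missing_policy: str = "drop",
) -> Dataset:
    """Assemble the HRV feature matrix over segments.

    Row *i* summarizes segment *i*. Features flagged undefined in any
    segment are handled per ``missing_policy``: ``"drop"`` removes the
    column (recorded in ``dropped_columns``), ``"impute"`` fills with the
    column median. ``label_level`` selects subclass or general-class labels.
    """
    if not segments:
        raise ValueError("no segments")
    if label_level not in ("subclass", "general_class"):
        raise ValueError("label_level must be 'subclass' or 'general_class'")
    if missing_policy not in ("drop", "impute"):
        raise ValueError("missing_policy must be 'drop' or 'impute'")
    rows = []
    schema: tuple[str, ...] | None = None
    for seg in segments:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = all_features(seg.rr)
        if schema is None:
            schema = fv.names
        elif fv.names != schema:
            raise ValueError("segments yield inconsistent feature schemas")
        rows.append(fv.values)
    X = pd.DataFrame(rows)
    incomplete = tuple(c for c in X.columns if X[c].isna().any())
    if missing_policy == "drop":
        X = X.drop(columns=list(incomplete))
        dropped = incomplete
    else:
        for c in incomplete:
            med = X[c].median()
            X[c] = X[c].fillna(0.0 if np.isnan(med) else med)
        dropped = ()
    labels = tuple(getattr(s, label_level) for s in segments)
    subjects = tuple(s.subject_id for s in segments)
    return Dataset(X.reset_index(drop=True), labels, subjects, dropped)


def scalogram(
    segment: Segment,
    scales: Sequence[float] | None = None,
    wavelet: str = "cmor1.5-1.0",
) -> Scalogram:
    """Continuous wavelet transform magnitude of a segment's RR sequence.

    The RR series is treated as a beat-indexed sequence with sampling period
    equal to its mean interval, the convention under which the returned
    scale-to-frequency map is in Hz. The default mother wavelet is the
    analytic (complex) Morlet.
    """
    x = segment.rr.intervals_ms - np.mean(segment.rr.intervals_ms)
    if scales is None:
        scales = np.geomspace(2, max(len(x) // 2, 4), 24)
    scales = np.asarray(scales, dtype=float)
    if len(x) < int(np.max(scales)):
        raise ValueError(
            f"segment length {len(x)} is shorter than the largest scale "
            f"({np.max(scales):.0f}) support"
        )
    dt = float(np.mean(segment.rr.intervals_ms)) / 1000.0
    coefs, freqs = pywt.cwt(x, scales, wavelet, sampling_period=dt)
    return Scalogram(np.abs(coefs), freqs, scales)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def mutual_information(x: np.ndarray, labels: np.ndarray, n_bins: int = 8) -> float:
    """MI (nats) between a continuous feature and a discrete label.

    The feature is discretized into equal-frequency bins (a filter-style
    estimator; deterministic, no nearest-neighbour randomness).
    """
    xb = _equal_frequency_bins(x, n_bins)
    joint = pd.crosstab(xb, labels).to_numpy().astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def rank_features(dataset: Dataset, top_k: int, n_bins: int = 8) -> list[str]:
    """Feature names ordered by decreasing mutual information with the label.

    Ties are broken by original column index, so the ranking is
    deterministic.
    """
    p = dataset.X.shape[1]
    if top_k > p:
        raise ValueError(f"top_k={top_k} exceeds feature count {p}")
    y = np.asarray(dataset.labels)
    scores = [
        (-mutual_information(dataset.X.iloc[:, j].to_numpy(), y, n_bins), j)
        for j in range(p)
    ]
    order = sorted(range(p), key=lambda j: scores[j])
    return [dataset.X.columns[j] for j in order[:top_k]]


def split_dataset(
    dataset: Dataset,
    train_fraction: float = 0.8,
    k_folds: int | None = None,
    group_aware: bool = False,
    seed: int = 0,
) -> SplitPlan:
    """Randomized train/test split, optionally subject-disjoint.

    With ``group_aware`` no subject contributes rows to both sides (the
    achieved fraction is then as close to the request as whole subjects
    allow). ``k_folds`` additionally partitions the indices (or subjects)
    into k folds covering every row exactly once.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    subjects = np.asarray(dataset.subjects)
    if group_aware:
        uniq = np.unique(subjects)
        if len(uniq) < 2:
            raise ValueError("group-aware split needs at least 2 subjects")
        order = rng.permutation(uniq)
        train_subj: list[str] = []
        count = 0
        target = train_fraction * n
        for s in order:
            size = int(np.sum(subjects == s))
            if count + size / 2 <= target or not train_subj:
                train_subj.append(s)
                count += size
            if count >= target:
                break
        train_subj_set = set(train_subj)
        if len(train_subj_set) == len(uniq):  # keep at least one test subject
            train_subj_set.discard(order[-1])
        train_idx = tuple(int(i) for i in np.flatnonzero(
            np.isin(subjects, list(train_subj_set))))
        test_idx = tuple(int(i) for i in np.flatnonzero(
            ~np.isin(subjects, list(train_subj_set))))
        fold_units: list[np.ndarray] = [
            np.flatnonzero(subjects == s) for s in rng.permutation(uniq)
        ]
    else:
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        train_idx = tuple(int(i) for i in np.sort(perm[:n_train]))
        test_idx = tuple(int(i) for i in np.sort(perm[n_train:]))
        fold_units = [np.array([i]) for i in rng.permutation(n)]
    folds: tuple[tuple[int, ...], ...] = ()
    if k_folds:
        if k_folds < 2 or k_folds > len(fold_units):
            raise ValueError("k_folds must be in [2, number of split units]")
        assignments: list[list[int]] = [[] for _ in range(k_folds)]
        for u, unit in enumerate(fold_units):
            assignments[u % k_folds].extend(int(i) for i in unit)
        folds = tuple(tuple(sorted(f)) for f in assignments)
    plan = SplitPlan(
        train_idx=train_idx,
        test_idx=test_idx,
        train_fraction=train_fraction,
        group_aware=group_aware,
        seed=seed,
        folds=folds,
    )
    if group_aware:
        overlap = set(subjects[list(plan.train_idx)]) & set(subjects[list(plan.test_idx)])
        assert not overlap, "subject leakage across the split"
    return plan


class ClassifierBackend(Protocol):
    """Contract for pluggable classifiers."""

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> None: ...

    def predict(self, features: np.ndarray) -> list[str]: ...


class _SklearnBackend:
    """Standardize features, then delegate to a scikit-learn estimator."""

    def __init__(self, estimator) -> None:
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self._pipe = make_pipeline(StandardScaler(), estimator)
        self._constant: str | None = None

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> None:
        labels = list(labels)
        if len(set(labels)) == 1:
            warnings.warn(
                "single-class training set: predictions will be constant",
                stacklevel=2,
            )
            self._constant = labels[0]
            return
        self._pipe.fit(np.asarray(features, dtype=float), labels)

    def predict(self, features: np.ndarray) -> list[str]:
        features = np.asarray(features, dtype=float)
        if len(features) == 0:
            return []
        if self._constant is not None:
            return [self._constant] * len(features)
        return list(self._pipe.predict(features))


class NearestCentroidBackend(_SklearnBackend):
    def __init__(self) -> None:
        from sklearn.neighbors import NearestCentroid

        super().__init__(NearestCentroid())


class KnnBackend(_SklearnBackend):
    def __init__(self, k: int = 5) -> None:
        from sklearn.neighbors import KNeighborsClassifier

        super().__init__(KNeighborsClassifier(n_neighbors=k))


def fit_predict(
    train: Dataset, test: Dataset, backend: ClassifierBackend | None = None
) -> list[str]:
    """Train a backend on ``train`` and return predicted labels for ``test``."""
    if tuple(train.X.columns) != tuple(test.X.columns):
        raise ValueError("train and test datasets must share a feature schema")
    backend = backend or KnnBackend()
    backend.fit(train.X.to_numpy(), train.labels)
    return backend.predict(test.X.to_numpy())
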