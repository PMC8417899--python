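"""HRV feature suite: time-domain, frequency-domain, geometric/Poincaré and
fractal/entropy indices computed from an RR interval series.

Conventions
-----------
* SDNN and related dispersion statistics use the sample (n-1) standard
  deviation. The Poincaré descriptors SD1/SD2 use population moments so the
  exact variance identity ``sd1**2 + sd2**2 == 2*var(NN)`` holds and the
  closed forms for constructed series are exact.
* Frequency analysis uses the Lomb-Scargle periodogram, which handles the
  irregular sampling of beat-anchored RR series natively; band powers are
  the integral of the one-sided spectral density over each band, in ms².
* Degenerate inputs (constant series, too-short records) yield NaN values
  accompanied by an entry in the result's ``flags`` set rather than an
  exception, so batch pipelines survive odd segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lombscargle

from .core import RrSeries

__all__ = [
    "DEFAULT_BANDS",
    "TimeDomainFeatures",
    "FreqDomainFeatures",
    "PoincareFeatures",
    "GeometricFeatures",
    "NonlinearFeatures",
    "HrvFeatureVector",
    "time_domain",
    "frequency_domain",
    "poincare",
    "triangular",
    "dfa",
    "entropy",
    "fractal_dimension",
    "all_features",
]

#: Canonical HRV spectral bands (Hz). The ULF/VLF edge is 0.0033 Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "ulf": (0.0, 0.0033),
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

#: Default RR histogram bin width: 1/128 s expressed in ms.
DEFAULT_BIN_WIDTH_MS = 1000.0 / 128.0


@dataclass(frozen=True)
class TimeDomainFeatures:
    mean_nn: float
    sdnn: float
    sdann: float
    sdnn_index: float
    rmssd: float
    pnn50: float
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class FreqDomainFeatures:
    ulf_power: float
    vlf_power: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    peak_freq: dict[str, float] = field(default_factory=dict)
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class PoincareFeatures:
    sd1: float
    sd2: float
    sd1_sd2_ratio: float
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class GeometricFeatures:
    tri: float
    tinn: float
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class NonlinearFeatures:
    dfa_alpha1: float
    dfa_alpha2: float
    apen: float
    sampen: float
    higuchi_fd: float
    katz_fd: float
    flags: frozenset = frozenset()


def time_domain(rr: RrSeries) -> TimeDomainFeatures:
    """Time-domain indices in milliseconds (pNN50 in percent).

    SDANN and the SDNN index are computed over non-overlapping 5-minute
    windows and flagged undefined for records shorter than 10 minutes.
    """
    iv = rr.intervals_ms
    if len(iv) < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.diff(iv)
    flags = set()
    sdann = sdnn_index = float("nan")
    span = rr.anchor_times_s[-1] - (rr.anchor_times_s[0] - iv[0] / 1000.0)
    if span >= 600.0:
        t0 = rr.anchor_times_s[0] - iv[0] / 1000.0
        window_idx = ((rr.anchor_times_s - t0) // 300.0).astype(int)
        means, sds = [], []
        for w in np.unique(window_idx):
            chunk = iv[window_idx == w]
            if len(chunk) >= 2:
                means.append(np.mean(chunk))
                sds.append(np.std(chunk, ddof=1))
        if len(means) >= 2:
            sdann = float(np.std(means, ddof=1))
            sdnn_index = float(np.mean(sds))
        else:
            flags.update({"sdann", "sdnn_index"})
    else:
        flags.update({"sdann", "sdnn_index"})
    return TimeDomainFeatures(
        mean_nn=float(np.mean(iv)),
        sdnn=float(np.std(iv, ddof=1)),
        sdann=sdann,
        sdnn_index=sdnn_index,
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.mean(np.abs(diffs) > 50.0)),
        flags=frozenset(flags),
    )


def _ls_psd(rr: RrSeries, f_max: float, oversample: int = 4):
    """One-sided Lomb-Scargle spectral density of the centred RR series.

    Scaled so that integrating the density across a spectral peak recovers
    the variance contribution (A²/2 for a sinusoid of amplitude A), giving
    band powers in ms².
    """
    t = rr.anchor_times_s
    y = rr.intervals_ms - np.mean(rr.intervals_ms)
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("RR series spans zero time")
    df = 1.0 / (oversample * span)
    freqs = np.arange(df, f_max + df / 2, df)
    power = lombscargle(t, y, 2 * np.pi * freqs)
    psd = 2.0 * power * span / len(y)
    return freqs, psd


def frequency_domain(
    rr: RrSeries, bands: dict[str, tuple[float, float]] | None = None
) -> FreqDomainFeatures:
    """Band powers (ms²) from the Lomb-Scargle periodogram of the RR series.

    Bands are half-open ``[lo, hi)``. Records shorter than 5 minutes give
    unstable LF/VLF estimates and trigger a warning.
    """
    bands = bands or DEFAULT_BANDS
    if len(rr) < 4:
        raise ValueError("need at least 4 intervals for spectral analysis")
    span = rr.anchor_times_s[-1] - rr.anchor_times_s[0]
    if span < 300.0:
        warnings.warn(
            f"record spans {span:.0f} s (< 5 min); LF and lower bands are unreliable",
            stacklevel=2,
        )
    f_max = max(hi for _, hi in bands.values())
    freqs, psd = _ls_psd(rr, f_max)
    flags = set()
    powers: dict[str, float] = {}
    peaks: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        if not np.any(sel):
            powers[name] = 0.0
            peaks[name] = float("nan")
            flags.add(f"{name}_peak")
            continue
        powers[name] = float(np.trapezoid(psd[sel], freqs[sel]))
        if np.max(psd[sel]) > 0:
            peaks[name] = float(freqs[sel][np.argmax(psd[sel])])
        else:
            peaks[name] = float("nan")
            flags.add(f"{name}_peak")
    if powers.get("hf", 0.0) > 0:
        ratio = powers["lf"] / powers["hf"]
    else:
        ratio = float("nan")
        flags.add("lf_hf_ratio")
    return FreqDomainFeatures(
        ulf_power=powers.get("ulf", 0.0),
        vlf_power=powers.get("vlf", 0.0),
        lf_power=powers.get("lf", 0.0),
        hf_power=powers.get("hf", 0.0),
        lf_hf_ratio=ratio,
        peak_freq=peaks,
        flags=frozenset(flags),
    )


def poincare(rr: RrSeries) -> PoincareFeatures:
    """Poincaré-plot descriptors via the variance identities.

    ``sd1² = var(successive differences)/2`` (short-term, the transverse
    spread of the fitted ellipse) and ``sd2² = 2·var(NN) − sd1²``
    (long-term, the longitudinal spread). Population moments are used, so
    ``sd1² + sd2² = 2·var(NN)`` holds exactly.
    """
    iv = rr.intervals_ms
    if len(iv) < 3:
        raise ValueError("need at least 3 intervals")
    diffs = np.diff(iv)
    sd1_sq = 0.5 * np.var(diffs)
    sd2_sq = max(2.0 * np.var(iv) - sd1_sq, 0.0)
    sd1 = float(np.sqrt(sd1_sq))
    sd2 = float(np.sqrt(sd2_sq))
    flags = set()
    if sd2 > 0:
        ratio = sd1 / sd2
    else:
        ratio = float("nan")
        flags.add("sd1_sd2_ratio")
    return PoincareFeatures(sd1=sd1, sd2=sd2, sd1_sd2_ratio=ratio, flags=frozenset(flags))


def _rr_histogram(iv: np.ndarray, bin_width_ms: float):
    lo = np.floor(iv.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(iv.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts, edges = np.histogram(iv, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return counts, centers


def triangular(
    rr: RrSeries, bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
) -> GeometricFeatures:
    """Triangular index and TINN from the RR histogram.

    TRI is the total interval count divided by the modal bin height. TINN is
    the base width (ms) of the best least-squares triangular fit to the
    histogram: a triangle rising from zero at N to the modal height at the
    modal bin and falling back to zero at M, optimized over (N, M).
    """
    iv = rr.intervals_ms
    if len(iv) < 2:
        raise ValueError("need at least 2 intervals")
    counts, centers = _rr_histogram(iv, bin_width_ms)
    mode = int(np.argmax(counts))
    tri = float(len(iv) / counts[mode])
    if np.count_nonzero(counts) <= 1:
        return GeometricFeatures(tri=tri, tinn=0.0)
    peak_x, peak_y = centers[mode], counts[mode]
    left_candidates = np.concatenate(
        ([centers[0] - bin_width_ms], centers[: mode + 1])
    )
    right_candidates = np.concatenate(
        (centers[mode:], [centers[-1] + bin_width_ms])
    )
    best = (np.inf, 0.0)
    for n_x in left_candidates:
        if n_x >= peak_x:
            continue
        rise = np.where(
            (centers > n_x) & (centers <= peak_x),
            peak_y * (centers - n_x) / (peak_x - n_x),
            0.0,
        )
        for m_x in right_candidates:
            if m_x <= peak_x:
                continue
            fall = np.where(
                (centers > peak_x) & (centers < m_x),
                peak_y * (m_x - centers) / (m_x - peak_x),
                0.0,
            )
            model = rise + fall
            err = float(np.sum((counts - model) ** 2))
            if err < best[0]:
                best = (err, m_x - n_x)
    return GeometricFeatures(tri=tri, tinn=float(best[1]))


def _box_sizes(lo: int, hi: int, n_points: int = 10) -> np.ndarray:
    sizes = np.unique(np.round(np.geomspace(lo, hi, n_points)).astype(int))
    return sizes[(sizes >= lo) & (sizes <= hi)]


def _dfa_fluctuation(y: np.ndarray, s: int) -> float:
    nb = len(y) // s
    segs = y[: nb * s].reshape(nb, s)
    t = np.arange(s, dtype=float)
    t_c = t - t.mean()
    denom = np.sum(t_c**2)
    x_mean = segs.mean(axis=1, keepdims=True)
    slope = (segs - x_mean) @ t_c / denom
    resid = segs - x_mean - slope[:, None] * t_c
    return float(np.sqrt(np.mean(resid**2)))


def dfa(
    rr: RrSeries,
    short_range: tuple[int, int] = (4, 16),
    long_range: tuple[int, int] = (16, 64),
) -> tuple[float, float]:
    """Detrended fluctuation analysis scaling exponents (α1, α2).

    The centred series is integrated, each box of size ``s`` is linearly
    detrended, and the RMS fluctuation F(s) is regressed on log s over the
    short-term (default 4-16 beats) and long-term (16-64 beats) ranges. A
    range needing more beats than ``n/4`` boxes of its largest size yields a
    NaN exponent. White noise gives α ≈ 0.5, a random walk ≈ 1.5.
    """
    iv = rr.intervals_ms
    if np.ptp(iv) == 0:
        return float("nan"), float("nan")
    y = np.cumsum(iv - np.mean(iv))

    def slope_for(box_range: tuple[int, int]) -> float:
        if len(iv) < 4 * box_range[1]:
            return float("nan")
        sizes = _box_sizes(*box_range)
        fs = np.array([_dfa_fluctuation(y, s) for s in sizes])
        ok = fs > 0
        if ok.sum() < 3:
            return float("nan")
        coef = np.polyfit(np.log(sizes[ok]), np.log(fs[ok]), 1)
        return float(coef[0])

    return slope_for(short_range), slope_for(long_range)


def _phi_counts(x: np.ndarray, m: int, r: float, self_match: bool) -> np.ndarray:
    n = len(x) - m + 1
    templates = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distance between all template pairs
    dist = np.max(
        np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1
    )
    match = dist <= r
    if not self_match:
        np.fill_diagonal(match, False)
    return match.sum(axis=1), n


def entropy(rr: RrSeries, m: int = 2, r: float = 0.2) -> tuple[float, float]:
    """Approximate and sample entropy (nats) with tolerance ``r``·SD.

    A zero-variance series returns (0, 0) by convention. Fewer than 50
    intervals gives unstable estimates and triggers a warning.
    """
    x = rr.intervals_ms
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for the chosen embedding length")
    if n < 50:
        warnings.warn("fewer than 50 intervals: entropy estimates are unstable",
                      stacklevel=2)
    sd = np.std(x)
    if sd == 0:
        return 0.0, 0.0
    tol = r * sd
    # ApEn: self-matches included, log averaged per template
    counts_m, n_m = _phi_counts(x, m, tol, self_match=True)
    counts_m1, n_m1 = _phi_counts(x, m + 1, tol, self_match=True)
    phi_m = np.mean(np.log(counts_m / n_m))
    phi_m1 = np.mean(np.log(counts_m1 / n_m1))
    apen = float(phi_m - phi_m1)
    # SampEn: self-matches excluded, totals ratioed
    b_counts, _ = _phi_counts(x[:-1], m, tol, self_match=False)
    a_counts, _ = _phi_counts(x, m + 1, tol, self_match=False)
    b_total = b_counts.sum()
    a_total = a_counts.sum()
    if a_total == 0 or b_total == 0:
        sampen = float("nan")
    else:
        sampen = float(-np.log(a_total / b_total))
    return apen, sampen


def _higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    n = len(x)
    ks = np.arange(1, kmax + 1)
    lengths = []
    for k in ks:
        lk = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (k * (len(idx) - 1))
            lk.append(dist * norm / k)
        lengths.append(np.mean(lk))
    lengths = np.asarray(lengths)
    ok = lengths > 0
    coef = np.polyfit(np.log(1.0 / ks[ok]), np.log(lengths[ok]), 1)
    return float(coef[0])


def _katz_fd(x: np.ndarray) -> float:
    # z-score the amplitudes so the waveform geometry (and hence the FD)
    # is invariant to the series' units and scale
    sd = np.std(x)
    if sd == 0:
        return 1.0
    z = (x - np.mean(x)) / sd
    length = float(np.sum(np.sqrt(1.0 + np.diff(z) ** 2)))
    idx = np.arange(len(z), dtype=float)
    d = float(np.max(np.sqrt(idx**2 + (z - z[0]) ** 2)))
    n = len(z) - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))


def fractal_dimension(rr: RrSeries, method: str = "higuchi", kmax: int = 10) -> float:
    """Fractal dimension of the RR series (Higuchi or Katz algorithm).

    Expected range is [1, 2] for a 1-D series: ~1 for a smooth curve, ~2 for
    white noise (Higuchi). Constant series return 1.0 by convention.
    """
    x = rr.intervals_ms
    if np.ptp(x) == 0:
        return 1.0
    if method == "higuchi":
        if len(x) < 100:
            warnings.warn("fewer than 100 intervals: Higuchi FD is unstable",
                          stacklevel=2)
        return _higuchi_fd(x, kmax)
    if method == "katz":
        return _katz_fd(x)
    raise ValueError(f"unknown fractal dimension method {method!r}")


#: Units of every feature in an HrvFeatureVector.
FEATURE_UNITS: dict[str, str] = {
    "mean_nn": "ms", "sdnn": "ms", "sdann": "ms", "sdnn_index": "ms",
    "rmssd": "ms", "pnn50": "%",
    "ulf_power": "ms^2", "vlf_power": "ms^2", "lf_power": "ms^2",
    "hf_power": "ms^2", "lf_hf_ratio": "", "lf_peak_freq": "Hz",
    "hf_peak_freq": "Hz",
    "sd1": "ms", "sd2": "ms", "sd1_sd2_ratio": "",
    "tri": "", "tinn": "ms",
    "dfa_alpha1": "", "dfa_alpha2": "", "apen": "nats", "sampen": "nats",
    "higuchi_fd": "", "katz_fd": "",
}


@dataclass(frozen=True)
class HrvFeatureVector:
    """Named union of all feature groups for one RR segment.

    ``values`` holds every feature exactly once; undefined features are NaN
    *and* listed in ``flags`` — never silently zero.
    """

    values: dict[str, float]
    flags: frozenset
    units: dict[str, str] = field(default_factory=lambda: dict(FEATURE_UNITS))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)


def all_features(
    rr: RrSeries, bands: dict[str, tuple[float, float]] | None = None
) -> HrvFeatureVector:
    """The full Table-style HRV feature vector for one segment.

    Component failures on degenerate input become flags, not exceptions;
    only an empty series raises.
    """
    if len(rr) == 0:
        raise ValueError("empty RR series")
    values: dict[str, float] = {}
    flags: set[str] = set()

    def run(fn, names, unpack):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = fn()
        except ValueError:
            for nm in names:
                values[nm] = float("nan")
                flags.add(nm)
            return
        unpack(result)

    def unpack_time(td: TimeDomainFeatures):
        for nm in ("mean_nn", "sdnn", "sdann", "sdnn_index", "rmssd", "pnn50"):
            values[nm] = getattr(td, nm)
        flags.update(td.flags)

    def unpack_freq(fd: FreqDomainFeatures):
        for nm in ("ulf_power", "vlf_power", "lf_power", "hf_power", "lf_hf_ratio"):
            values[nm] = getattr(fd, nm)
        values["lf_peak_freq"] = fd.peak_freq.get("lf", float("nan"))
        values["hf_peak_freq"] = fd.peak_freq.get("hf", float("nan"))
        for nm in ("lf_peak_freq", "hf_peak_freq"):
            if np.isnan(values[nm]):
                flags.add(nm)
        if "lf_hf_ratio" in fd.flags:
            flags.add("lf_hf_ratio")

    def unpack_poincare(pc: PoincareFeatures):
        values["sd1"], values["sd2"] = pc.sd1, pc.sd2
        values["sd1_sd2_ratio"] = pc.sd1_sd2_ratio
        flags.update(pc.flags)

    def unpack_geom(gm: GeometricFeatures):
        values["tri"], values["tinn"] = gm.tri, gm.tinn

    def unpack_dfa(slopes):
        values["dfa_alpha1"], values["dfa_alpha2"] = slopes
        for nm in ("dfa_alpha1", "dfa_alpha2"):
            if np.isnan(values[nm]):
                flags.add(nm)

    def unpack_entropy(ents):
        values["apen"], values["sampen"] = ents
        if np.ptp(rr.intervals_ms) == 0:
            flags.update({"apen", "sampen"})
        if np.isnan(values["sampen"]):
            flags.add("sampen")

    run(lambda: time_domain(rr),
        ("mean_nn", "sdnn", "sdann", "sdnn_index", "rmssd", "pnn50"), unpack_time)
    run(lambda: frequency_domain(rr, bands),
        ("ulf_power", "vlf_power", "lf_power", "hf_power", "lf_hf_ratio",
         "lf_peak_freq", "hf_peak_freq"), unpack_freq)
    run(lambda: poincare(rr), ("sd1", "sd2", "sd1_sd2_ratio"), unpack_poincare)
    run(lambda: triangular(rr), ("tri", "tinn"), unpack_geom)
    run(lambda: dfa(rr), ("dfa_alpha1", "dfa_alpha2"), unpack_dfa)
    run(lambda: entropy(rr), ("apen", "sampen"), unpack_entropy)

    for method, nm in (("higuchi", "higuchi_fd"), ("katz", "katz_fd")):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values[nm] = fractal_dimension(rr, method)
            if np.ptp(rr.intervals_ms) == 0:
                flags.add(nm)
        except ValueError:
            values[nm] = float("nan")
            flags.add(nm)

    return HrvFeatureVector(values=values, flags=frozenset(flags))
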