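"""Seeded synthetic RR series, ECG traces, and multi-subject studies.

The generator provides ground truth for every downstream stage: RR interval
series with band-limited autonomic modulation (LF around 0.1 Hz, HF around
0.25 Hz, within the canonical 0.04–0.15 and 0.15–0.4 Hz bands), ECG traces
built from a sum-of-Gaussians PQRST template with known R-apex times, and
whole studies in which sound-stimulus epochs shift the autonomic parameters
by a controllable effect size.

RR intervals are generated beat by beat: the modulation waveforms are
evaluated at each cumulative beat time and added to the mean interval, with
optional i.i.d. Gaussian jitter. This is a simplification of integral pulse
frequency modulation, adequate for recovering modulation frequencies with a
Lomb-Scargle periodogram.

Noise is added after clean synthesis (baseline wander, mains interference,
broadband Gaussian noise at a target SNR), and the clean trace is kept so
filtering stages can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import EcgRecord, RrSeries
from .evaluate import ClassHierarchy
from .schedule import Epoch, StimulusSchedule

__all__ = [
    "RrGenConfig",
    "EcgGenConfig",
    "StimulusEffect",
    "SynthEcg",
    "StudyRecord",
    "SyntheticStudy",
    "generate_rr_series",
    "generate_ecg",
    "generate_study",
    "DEFAULT_WAVE_PARAMS",
]

MIN_ECG_SAMPLE_RATE_HZ = 250.0
MIN_EPOCH_DURATION_S = 10.0

#: PQRST template: per wave (amplitude mV, Gaussian sigma s, offset from R s).
#: Offsets and widths are scaled by the local RR so complexes never collide.
DEFAULT_WAVE_PARAMS: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 0.025, -0.20),
    "Q": (-0.10, 0.010, -0.035),
    "R": (1.00, 0.012, 0.0),
    "S": (-0.15, 0.010, 0.035),
    "T": (0.30, 0.050, 0.30),
}


@dataclass(frozen=True)
class StimulusEffect:
    """Additive shift of the RR generator parameters while a stimulus plays."""

    mean_rr_ms: float = 0.0
    lf_amp_ms: float = 0.0
    hf_amp_ms: float = 0.0


@dataclass(frozen=True)
class RrGenConfig:
    """Parameters of the RR-interval generator.

    lf_mod / hf_mod are (frequency Hz, amplitude ms) pairs; frequencies must
    lie in (0, 0.5] Hz (at most the per-beat Nyquist for ~1 s beats).
    stimulus_effects maps a subclass label to the parameter shift applied
    while that stimulus is on.
    """

    duration_s: float = 300.0
    mean_rr_ms: float = 900.0
    lf_mod: tuple[float, float] = (0.1, 30.0)
    hf_mod: tuple[float, float] = (0.25, 20.0)
    jitter_sd_ms: float = 5.0
    stimulus_effects: Mapping[str, StimulusEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        for name, (f, a) in (("lf_mod", self.lf_mod), ("hf_mod", self.hf_mod)):
            if a != 0 and not (0 < f <= 0.5):
                raise ValueError(f"{name} frequency must be in (0, 0.5] Hz")
            if a < 0:
                raise ValueError(f"{name} amplitude must be >= 0")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")


@dataclass(frozen=True)
class EcgGenConfig:
    """Parameters of the ECG synthesizer.

    The sample-rate floor of 250 Hz reflects the minimum acquisition rate
    adequate for ECG bandwidth; lower rates are rejected. Noise terms are
    optional: baseline_wander and mains are (frequency Hz, amplitude mV)
    sinusoids, broadband_snr_db sets Gaussian noise power relative to the
    clean trace (None disables it).
    """

    sample_rate_hz: float = 360.0
    wave_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVE_PARAMS)
    )
    baseline_wander: tuple[float, float] | None = None
    mains: tuple[float, float] | None = None
    broadband_snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz < MIN_ECG_SAMPLE_RATE_HZ:
            raise ValueError(
                f"sample_rate_hz must be >= {MIN_ECG_SAMPLE_RATE_HZ:.0f} Hz for ECG"
            )
        for term in (self.baseline_wander, self.mains):
            if term is not None and (term[0] <= 0 or term[1] < 0):
                raise ValueError("noise terms need positive frequency, amplitude >= 0")
        for wave, (_, width, _) in self.wave_params.items():
            if width <= 0:
                raise ValueError(f"wave {wave!r} width must be positive")


@dataclass(frozen=True)
class SynthEcg:
    """Synthesized ECG with its clean version and ground-truth R apexes."""

    record: EcgRecord
    clean: EcgRecord
    r_times_s: np.ndarray


@dataclass(frozen=True)
class StudyRecord:
    subject_id: str
    ecg: SynthEcg | None
    schedule: StimulusSchedule
    rr_truth: RrSeries
    labels: tuple[tuple[str, str], ...]  # (general_class, subclass) per epoch


@dataclass(frozen=True)
class SyntheticStudy:
    hierarchy: ClassHierarchy
    records: tuple[StudyRecord, ...]


def _modulation(
    t_s: float, cfg: RrGenConfig, effect: StimulusEffect | None
) -> float:
    lf_f, lf_a = cfg.lf_mod
    hf_f, hf_a = cfg.hf_mod
    mean = cfg.mean_rr_ms
    if effect is not None:
        mean += effect.mean_rr_ms
        lf_a = max(lf_a + effect.lf_amp_ms, 0.0)
        hf_a = max(hf_a + effect.hf_amp_ms, 0.0)
    value = mean
    if lf_a:
        value += lf_a * np.sin(2 * np.pi * lf_f * t_s)
    if hf_a:
        value += hf_a * np.sin(2 * np.pi * hf_f * t_s)
    return value


def generate_rr_series(
    config: RrGenConfig, schedule: StimulusSchedule | None = None
) -> RrSeries:
    """Generate a beat-by-beat RR series under optional stimulus effects.

    The deterministic part (mean + LF + HF modulation evaluated at the
    running beat time) must stay positive; configurations whose modulation
    amplitudes could drive intervals non-positive are rejected up front.
    Jitter is i.i.d. Gaussian per beat. Identical configs and seeds give
    bit-identical output.
    """
    worst_amp = config.lf_mod[1] + config.hf_mod[1]
    worst_shift = 0.0
    if schedule is not None:
        for eff in config.stimulus_effects.values():
            amp = (
                max(config.lf_mod[1] + eff.lf_amp_ms, 0)
                + max(config.hf_mod[1] + eff.hf_amp_ms, 0)
            )
            worst_amp = max(worst_amp, amp)
            worst_shift = min(worst_shift, eff.mean_rr_ms)
    if worst_amp >= config.mean_rr_ms + worst_shift:
        raise ValueError(
            "modulation amplitudes "
            f"({worst_amp:.1f} ms) would drive RR intervals <= 0 at mean "
            f"{config.mean_rr_ms + worst_shift:.1f} ms; reduce the amplitudes"
        )
    rng = np.random.default_rng(config.seed)
    intervals: list[float] = []
    anchors: list[float] = []
    t = 0.0
    while t < config.duration_s:
        effect = None
        if schedule is not None:
            epoch = schedule.epoch_at(t)
            if epoch is not None:
                effect = config.stimulus_effects.get(epoch.subclass)
        rr = _modulation(t, config, effect)
        if config.jitter_sd_ms:
            rr += rng.normal(0.0, config.jitter_sd_ms)
        if rr <= 0:
            raise ValueError(
                f"generated interval {rr:.1f} ms <= 0 at t={t:.1f} s; "
                "jitter too large for the configured mean"
            )
        t += rr / 1000.0
        intervals.append(rr)
        anchors.append(t)
    return RrSeries(np.array(intervals), np.array(anchors))


def generate_ecg(rr: RrSeries, config: EcgGenConfig) -> SynthEcg:
    """Render an ECG trace for an RR series.

    One PQRST complex is placed per beat (a sum of Gaussian bumps whose
    widths and offsets scale with the local RR), with the R apex at the beat
    time. Noise terms — baseline wander, mains interference, broadband
    Gaussian noise at the configured SNR — are added after clean synthesis;
    the clean trace and the exact R-apex times are returned alongside.
    """
    if len(rr) == 0:
        raise ValueError("RR series must be non-empty")
    fs = config.sample_rate_hz
    beat_times = np.concatenate(
        ([rr.anchor_times_s[0] - rr.intervals_ms[0] / 1000.0], rr.anchor_times_s)
    )
    beat_times = beat_times - beat_times[0]
    lead_in = 0.3  # complete the first complex's P wave before beat 0
    duration = lead_in + beat_times[-1] + 0.4  # room for the last T wave
    n = int(np.round(duration * fs)) + 1
    t = np.arange(n) / fs - lead_in
    clean = np.zeros(n)
    # local RR per beat (s), last beat reuses the final interval
    local_rr = np.empty(len(beat_times))
    local_rr[:-1] = rr.intervals_ms / 1000.0
    local_rr[-1] = rr.intervals_ms[-1] / 1000.0
    for tb, rr_s in zip(beat_times, local_rr):
        scale = rr_s / 1.0  # template tuned for a 1 s beat
        for amp, width, offset in config.wave_params.values():
            mu = tb + offset * scale
            sig = width * max(scale, 0.3)
            lo = max(int((mu - 5 * sig + lead_in) * fs), 0)
            hi = min(int((mu + 5 * sig + lead_in) * fs) + 1, n)
            if lo < hi:
                clean[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sig) ** 2)
    noisy = clean.copy()
    rng = np.random.default_rng(config.seed)
    if config.baseline_wander is not None:
        f, a = config.baseline_wander
        noisy += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if config.mains is not None:
        f, a = config.mains
        if f >= fs / 2:
            raise ValueError("mains frequency must be below Nyquist")
        noisy += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if config.broadband_snr_db is not None:
        p_signal = np.mean(clean**2)
        p_noise = p_signal / 10 ** (config.broadband_snr_db / 10)
        noisy += rng.normal(0.0, np.sqrt(p_noise), n)
    return SynthEcg(
        record=EcgRecord(noisy, fs, start_time_s=-lead_in),
        clean=EcgRecord(clean, fs, start_time_s=-lead_in),
        r_times_s=beat_times,
    )


def default_stimulus_effects(
    hierarchy: ClassHierarchy, effect_size: float
) -> dict[str, StimulusEffect]:
    """A graded effect model over the hierarchy's leaf classes.

    Leaf class k (in hierarchy order, k = 0..K-1) shifts the autonomic
    parameters in proportion to its normalized rank u = k/(K-1): mean RR by
    ``+40*u*effect_size`` ms, LF amplitude by ``+25*u*effect_size`` ms and HF
    amplitude by ``-12*u*effect_size`` ms. With ``effect_size = 0`` all
    classes share identical generator parameters. The model is an assumption
    of this package — a monotone sympathovagal gradient across the stimulus
    order — not an empirical claim.
    """
    leaves = hierarchy.leaf_labels
    k = len(leaves)
    effects = {}
    for idx, leaf in enumerate(leaves):
        u = idx / (k - 1) if k > 1 else 0.0
        effects[leaf] = StimulusEffect(
            mean_rr_ms=40.0 * u * effect_size,
            lf_amp_ms=25.0 * u * effect_size,
            hf_amp_ms=-12.0 * u * effect_size,
        )
    return effects


def generate_study(
    hierarchy: ClassHierarchy,
    n_subjects: int,
    epochs_per_class: int,
    epoch_duration_s: float,
    effect_size: float,
    rr_config: RrGenConfig | None = None,
    ecg_config: EcgGenConfig | None = None,
    *,
    silence_s: float = 5.0,
    include_ecg: bool = True,
    seed: int | None = None,
) -> SyntheticStudy:
    """Generate a full multi-subject study with per-epoch stimulus labels.

    Each subject receives a randomized order of ``epochs_per_class`` epochs
    of every leaf class, separated by ``silence_s`` of unstimulated
    recording. Stimulus effects are the graded defaults scaled by
    ``effect_size`` unless ``rr_config.stimulus_effects`` is non-empty, in
    which case those shifts are used as given (still scaled by effect_size).
    Per-subject random streams are derived from the top-level seed by a
    fixed offset so subjects are decoupled.
    """
    if hierarchy.n_leaves == 0:
        raise ValueError("hierarchy must not be empty")
    if epoch_duration_s < MIN_EPOCH_DURATION_S:
        raise ValueError(
            f"epoch_duration_s must be >= {MIN_EPOCH_DURATION_S:.0f} s "
            "(minimum stimulus duration)"
        )
    if n_subjects < 1 or epochs_per_class < 1:
        raise ValueError("n_subjects and epochs_per_class must be >= 1")
    rr_config = rr_config or RrGenConfig()
    if seed is None:
        seed = rr_config.seed
    if rr_config.stimulus_effects:
        effects = {
            lab: StimulusEffect(
                e.mean_rr_ms * effect_size,
                e.lf_amp_ms * effect_size,
                e.hf_amp_ms * effect_size,
            )
            for lab, e in rr_config.stimulus_effects.items()
        }
    else:
        effects = default_stimulus_effects(hierarchy, effect_size)
    leaves = hierarchy.leaf_labels
    records = []
    for s in range(n_subjects):
        subject_seed = int(seed) + 10_000 * (s + 1)
        order_rng = np.random.default_rng(subject_seed)
        labels = [leaf for leaf in leaves for _ in range(epochs_per_class)]
        order_rng.shuffle(labels)
        epochs = []
        t = silence_s
        for lab in labels:
            epochs.append(
                Epoch(t, epoch_duration_s, hierarchy.general_of(lab), lab)
            )
            t += epoch_duration_s + silence_s
        sched = StimulusSchedule(epochs)
        cfg = replace(
            rr_config,
            duration_s=t,
            stimulus_effects=effects,
            seed=subject_seed + 1,
        )
        rr = generate_rr_series(cfg, schedule=sched)
        ecg = None
        if include_ecg:
            ecg_cfg = ecg_config or EcgGenConfig()
            ecg = generate_ecg(rr, replace(ecg_cfg, seed=subject_seed + 2))
        records.append(
            StudyRecord(
                subject_id=f"S{s:03d}",
                ecg=ecg,
                schedule=sched,
                rr_truth=rr,
                labels=tuple((e.general_class, e.subclass) for e in sched),
            )
        )
    if not include_ecg and ecg_config is not None:
        warnings.warn("ecg_config ignored because include_ecg=False", stacklevel=2)
    return SyntheticStudy(hierarchy=hierarchy, records=tuple(records))
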