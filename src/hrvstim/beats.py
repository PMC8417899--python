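"""R-peak detection (Pan-Tompkins) and RR/NN series computation.

The detector follows the classic stage sequence: QRS-enhancement bandpass,
five-point derivative, squaring, moving-window integration, and adaptive
dual thresholds with a refractory period and a search-back pass for missed
beats. Detected fiducials are refined to the local maximum of the bandpassed
ECG so reported times are R apexes rather than integrator crossings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BeatTimes, EcgRecord, RrSeries
from .preprocess import bandpass

__all__ = [
    "PanTompkinsParams",
    "detect_r_peaks",
    "rr_from_beats",
    "abnormal_interval_mask",
    "nn_series",
]


@dataclass(frozen=True)
class PanTompkinsParams:
    """Detector constants, exposed for tuning.

    Defaults follow common practice: 5-15 Hz QRS band, 150 ms integration
    window, 200 ms refractory period, and running-estimate update factors of
    1/8 for the accepted-peak level and 1/4 toward threshold.
    """

    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    derivative_points: int = 5
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    signal_update: float = 0.125
    threshold_fraction: float = 0.25
    searchback_factor: float = 1.66
    apex_window_s: float = 0.050


def _integrated_signal(ecg: EcgRecord, params: PanTompkinsParams) -> tuple[np.ndarray, np.ndarray]:
    """Bandpassed trace and the squared-derivative moving integral."""
    fs = ecg.sample_rate_hz
    bp = bandpass(ecg, params.band_low_hz, params.band_high_hz).samples
    # classic 5-point derivative: (1/8)(-x[n-2] - 2x[n-1] + 2x[n+1] + x[n+2])
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv**2
    win = max(int(round(params.integration_window_s * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    return bp, integrated


def detect_r_peaks(
    ecg: EcgRecord, params: PanTompkinsParams | None = None
) -> BeatTimes:
    """Detect R-peak apex times with the Pan-Tompkins algorithm.

    Requires at least 3 s of signal. A flat record yields an empty result
    with a warning; a sample rate below 250 Hz triggers a warning but the
    detector still runs.
    """
    params = params or PanTompkinsParams()
    fs = ecg.sample_rate_hz
    if ecg.duration_s < 3.0:
        raise ValueError("record must be at least 3 s long")
    if fs < 250:
        warnings.warn(
            f"sample rate {fs} Hz is below the recommended 250 Hz", stacklevel=2
        )
    if np.ptp(ecg.samples) == 0:
        warnings.warn("flat signal: no R-peaks detected", stacklevel=2)
        return BeatTimes(np.empty(0))
    bp, integ = _integrated_signal(ecg, params)
    refractory = int(round(params.refractory_s * fs))
    candidates, _ = sps.find_peaks(integ, distance=max(refractory, 1))
    if candidates.size == 0:
        warnings.warn("no candidate peaks found", stacklevel=2)
        return BeatTimes(np.empty(0))

    # adaptive dual-threshold classification of candidate peaks
    lead_in = integ[: int(min(2 * fs, len(integ)))]
    spk = float(np.max(lead_in)) * 0.5  # running signal-peak estimate
    npk = float(np.mean(lead_in)) * 0.5  # running noise-peak estimate
    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npk + params.threshold_fraction * (spk - npk)

    for idx in candidates:
        peak = integ[idx]
        if peak > threshold():
            if accepted and idx - accepted[-1] < refractory:
                continue
            # search-back: a long gap since the last beat suggests a missed
            # low-amplitude beat; rescan the gap with half the threshold
            if len(rr_history) >= 2:
                mean_rr = float(np.mean(rr_history[-8:]))
                gap = idx - accepted[-1]
                if gap > params.searchback_factor * mean_rr:
                    seg = integ[accepted[-1] + refractory : idx - refractory // 2]
                    if seg.size:
                        rel = int(np.argmax(seg))
                        if seg[rel] > 0.5 * threshold():
                            missed = accepted[-1] + refractory + rel
                            rr_history.append(missed - accepted[-1])
                            accepted.append(missed)
                            spk = 0.25 * seg[rel] + 0.75 * spk
            if accepted:
                rr_history.append(idx - accepted[-1])
            accepted.append(idx)
            spk = params.signal_update * peak + (1 - params.signal_update) * spk
        else:
            npk = params.signal_update * peak + (1 - params.signal_update) * npk

    if not accepted:
        warnings.warn("no peaks exceeded the adaptive threshold", stacklevel=2)
        return BeatTimes(np.empty(0))

    # refine each fiducial to the local maximum of the bandpassed ECG
    half = int(round(params.apex_window_s * fs))
    apexes = []
    for idx in accepted:
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, len(bp))
        apexes.append(lo + int(np.argmax(bp[lo:hi])))
    apexes = np.unique(apexes)
    # enforce refractory after refinement
    keep = [apexes[0]]
    for idx in apexes[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(idx)
    times = ecg.start_time_s + np.asarray(keep) / fs
    return BeatTimes(times)


def rr_from_beats(beats: BeatTimes) -> RrSeries:
    """Successive R-R intervals in ms, anchored at each interval's second beat."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to form RR intervals")
    times = beats.times_s
    return RrSeries(np.diff(times) * 1000.0, times[1:])


def abnormal_interval_mask(
    rr: RrSeries,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    median_tolerance: float = 0.20,
    median_window: int = 11,
) -> np.ndarray:
    """Flag intervals that are physiologically implausible or locally deviant.

    An interval is flagged when it falls outside [min_ms, max_ms] or deviates
    from the local running median (window of ``median_window`` beats) by more
    than ``median_tolerance``. Flagged intervals are excluded from NN ("normal
    to normal") statistics. The rule is a documented heuristic, not a
    clinical ectopy classifier.
    """
    iv = rr.intervals_ms
    mask = (iv < min_ms) | (iv > max_ms)
    if len(iv) >= 3:
        med = sps.medfilt(iv, kernel_size=min(median_window, len(iv) | 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs(iv - med) / med
        mask |= dev > median_tolerance
    return mask


def nn_series(rr: RrSeries, **kwargs) -> RrSeries:
    """RR series restricted to normal (unflagged) intervals."""
    mask = abnormal_interval_mask(rr, **kwargs)
    if mask.all():
        raise ValueError("every interval was flagged abnormal")
    return RrSeries(rr.intervals_ms[~mask], rr.anchor_times_s[~mask])
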