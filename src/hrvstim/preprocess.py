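"""ECG conditioning: baseline-wander removal, mains cancellation, bandpass
filtering, and SNR-based assessment of the filtering stage.

All filters preserve signal length and are zero-phase (moving-average
baselines are symmetric; IIR stages run forward-backward), so R-peak
latencies are not shifted by preprocessing.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter

from .core import EcgRecord

__all__ = ["remove_baseline", "remove_mains", "bandpass", "snr_db", "SNR_CEILING_DB"]

#: Reported SNR is capped here when the residual is exactly zero.
SNR_CEILING_DB = 120.0


def _odd_window(window_s: float, fs: float) -> int:
    n = max(int(round(window_s * fs)), 1)
    return n if n % 2 == 1 else n + 1


def remove_baseline(
    ecg: EcgRecord,
    window_s: float = 0.6,
    first_window_s: float = 0.2,
    smooth_hz: float = 1.0,
) -> EcgRecord:
    """Subtract a two-pass cascaded moving-filter baseline estimate.

    The baseline is estimated by two cascaded moving medians (defaults
    0.2 s then 0.6 s): the short pass rejects QRS complexes, the long pass
    rejects P and T waves, leaving the sub-hertz wander. Medians rather
    than means keep beat-periodic energy out of the estimate, which a
    plain moving-average cascade leaks back into the signal. The stepwise
    median output is smoothed with a zero-phase low-pass (default 1 Hz),
    and the estimate is refined once on the residual, which cancels the
    small duty-cycle offset of the median and makes the operation
    approximately idempotent.
    """
    fs = ecg.sample_rate_hz
    if window_s * fs < 3:
        raise ValueError("window_s must span at least 3 samples")
    n1 = _odd_window(first_window_s, fs)
    n2 = _odd_window(window_s, fs)
    if max(n1, n2) > len(ecg.samples):
        raise ValueError("baseline window longer than the record")

    def estimate(x: np.ndarray) -> np.ndarray:
        bl = median_filter(x, size=n1, mode="nearest")
        bl = median_filter(bl, size=n2, mode="nearest")
        if smooth_hz and smooth_hz < fs / 2:
            sos = signal.butter(4, smooth_hz, fs=fs, output="sos")
            bl = signal.sosfiltfilt(sos, bl)
        return bl

    baseline = estimate(ecg.samples)
    baseline = baseline + estimate(ecg.samples - baseline)
    return EcgRecord(ecg.samples - baseline, fs, ecg.start_time_s)


def remove_mains(ecg: EcgRecord, mains_hz: float = 50.0, quality: float = 30.0) -> EcgRecord:
    """Cancel powerline interference with a zero-phase IIR notch.

    ``mains_hz`` is 50 or 60 Hz depending on the power grid; ``quality`` is
    the notch Q factor (center frequency / -3 dB bandwidth).
    """
    fs = ecg.sample_rate_hz
    if mains_hz >= fs / 2:
        raise ValueError(
            f"mains frequency {mains_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    if mains_hz <= 0 or quality <= 0:
        raise ValueError("mains_hz and quality must be positive")
    b, a = signal.iirnotch(mains_hz, quality, fs=fs)
    filtered = signal.filtfilt(b, a, ecg.samples)
    return EcgRecord(filtered, fs, ecg.start_time_s)


def bandpass(ecg: EcgRecord, low_hz: float, high_hz: float, order: int = 4) -> EcgRecord:
    """Zero-phase Butterworth bandpass (highpass disabled when low_hz == 0)."""
    fs = ecg.sample_rate_hz
    nyq = fs / 2
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"need 0 <= low < high < Nyquist; got [{low_hz}, {high_hz}] at fs={fs}"
        )
    if low_hz == 0:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    else:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
        )
    filtered = signal.sosfiltfilt(sos, ecg.samples)
    return EcgRecord(filtered, fs, ecg.start_time_s)


def snr_db(reference: EcgRecord, test: EcgRecord) -> float:
    """Signal-to-noise ratio of ``test`` against a clean ``reference``.

    ``10*log10(P_ref / P_residual)`` with the residual ``test - reference``;
    capped at ``SNR_CEILING_DB`` when the residual vanishes.
    """
    if len(reference.samples) != len(test.samples):
        raise ValueError("records must have equal length")
    if reference.sample_rate_hz != test.sample_rate_hz:
        raise ValueError("records must share a sample rate")
    p_signal = np.mean(reference.samples**2)
    p_noise = np.mean((test.samples - reference.samples) ** 2)
    if p_noise == 0:
        return SNR_CEILING_DB
    value = 10.0 * np.log10(p_signal / p_noise)
    return float(min(value, SNR_CEILING_DB))
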