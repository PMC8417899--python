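"""Core signal containers shared across the pipeline.

The three containers mirror the stages of an HRV study: a sampled ECG
voltage trace (:class:`EcgRecord`), the detected R-peak times
(:class:`BeatTimes`), and the beat-to-beat interval series
(:class:`RrSeries`) on which all HRV indices are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EcgRecord", "BeatTimes", "RrSeries"]


@dataclass(frozen=True)
class EcgRecord:
    """A single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in millivolts.
    sample_rate_hz : float
        Sampling rate in Hz; must be positive.
    start_time_s : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return (len(self.samples) - 1) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.start_time_s + np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class BeatTimes:
    """R-peak occurrence times in seconds, strictly increasing."""

    times_s: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", times)
        if times.ndim != 1:
            raise ValueError("times_s must be 1-D")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class RrSeries:
    """Successive R-R intervals in milliseconds.

    ``anchor_times_s[i]`` is the timestamp of the *second* beat of interval
    ``i``, so an interval is attributed to the moment it completes.
    """

    intervals_ms: np.ndarray
    anchor_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        object.__setattr__(self, "intervals_ms", iv)
        if iv.ndim != 1 or iv.size == 0:
            raise ValueError("intervals_ms must be a non-empty 1-D array")
        if np.any(iv <= 0):
            raise ValueError("RR intervals must be positive")
        if self.anchor_times_s is None:
            object.__setattr__(self, "anchor_times_s", np.cumsum(iv) / 1000.0)
        else:
            at = np.asarray(self.anchor_times_s, dtype=float)
            if at.shape != iv.shape:
                raise ValueError("anchor_times_s must match intervals_ms in length")
            object.__setattr__(self, "anchor_times_s", at)

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def duration_s(self) -> float:
        """Span from the start of the first interval to the last anchor."""
        first_start = self.anchor_times_s[0] - self.intervals_ms[0] / 1000.0
        return float(self.anchor_times_s[-1] - first_start)
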