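"""Stimulus schedules: which sound class was playing when.

A schedule is an ordered list of non-overlapping epochs, each tagged with a
general class (e.g. ``consonant`` / ``dissonant`` / ``noise``) and a subclass
(e.g. a specific harmonic interval). Epoch spans are half-open
``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = ["Epoch", "StimulusSchedule"]


@dataclass(frozen=True)
class Epoch:
    onset_s: float
    duration_s: float
    general_class: str
    subclass: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("epoch onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StimulusSchedule:
    epochs: tuple[Epoch, ...]

    def __init__(self, epochs: Iterable[Epoch]) -> None:
        eps = tuple(sorted(epochs, key=lambda e: e.onset_s))
        for a, b in zip(eps, eps[1:]):
            if b.onset_s < a.end_s:
                raise ValueError(
                    f"overlapping epochs: [{a.onset_s}, {a.end_s}) and "
                    f"[{b.onset_s}, {b.end_s})"
                )
        object.__setattr__(self, "epochs", eps)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    @property
    def end_s(self) -> float:
        return self.epochs[-1].end_s if self.epochs else 0.0

    def epoch_at(self, t_s: float) -> Epoch | None:
        """Epoch whose half-open span contains ``t_s``, or None (silence)."""
        for e in self.epochs:
            if e.onset_s <= t_s < e.end_s:
                return e
        return None
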