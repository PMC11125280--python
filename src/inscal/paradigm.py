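"""Stimulation paradigms for pulsed infrared neural stimulation (INS).

Two paradigms are supported:

``multi_train``
    60 s trial: 10 s baseline, then six 0.5 s pulse trains (0.25 ms pulses at
    200 Hz, 100 pulses per train) separated by 2.5 s gaps — an 18 s
    stimulation epoch — followed by 32 s of recovery.

``long_train``
    30 s trial: 3 s baseline, one 2 s pulse train (400 pulses at 200 Hz),
    25 s recovery.  Used for distal (contralateral) response measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["StimulusParadigm", "ParadigmError", "make_paradigm"]


class ParadigmError(ValueError):
    """Raised for an unknown paradigm kind or inconsistent timing fields."""


@dataclass(frozen=True)
class StimulusParadigm:
    """Complete temporal description of one INS trial.

    Times are seconds except ``pulse_width_ms``; ``radiant_exposure`` is the
    per-pulse energy density at the fiber tip in J/cm².
    """

    pulse_width_ms: float
    pulse_rate_hz: float
    train_duration_s: float
    n_trains: int
    train_interval_s: float
    trial_length_s: float
    baseline_length_s: float
    radiant_exposure: float
    label: str

    def __post_init__(self) -> None:
        if self.radiant_exposure < 0:
            raise ParadigmError("radiant_exposure must be >= 0")
        if self.n_trains < 1:
            raise ParadigmError("n_trains must be >= 1")
        ppt = self.pulse_rate_hz * self.train_duration_s
        if ppt <= 0 or abs(ppt - round(ppt)) > 1e-9:
            raise ParadigmError(
                f"pulse_rate x train_duration = {ppt} is not a positive integer"
            )
        if self.baseline_length_s + self.stim_epoch_s > self.trial_length_s + 1e-9:
            raise ParadigmError("baseline + stimulation epoch exceed trial length")

    @property
    def pulses_per_train(self) -> int:
        return int(round(self.pulse_rate_hz * self.train_duration_s))

    @property
    def train_period_s(self) -> float:
        """Onset-to-onset period of successive trains."""
        return self.train_duration_s + self.train_interval_s

    @property
    def stim_epoch_s(self) -> float:
        """Duration of the stimulation epoch (all train periods)."""
        return self.n_trains * self.train_period_s

    @property
    def train_onsets_s(self) -> np.ndarray:
        """Onset time of each pulse train, seconds from trial start."""
        return self.baseline_length_s + np.arange(self.n_trains) * self.train_period_s

    @property
    def stim_window_s(self) -> tuple[float, float]:
        """Half-open [start, end) of the stimulation epoch in trial time."""
        start = self.baseline_length_s
        return (start, start + self.stim_epoch_s)

    def at_exposure(self, radiant_exposure: float) -> "StimulusParadigm":
        """Copy of this paradigm at a different radiant exposure."""
        return replace(self, radiant_exposure=radiant_exposure)


def make_paradigm(kind: str, radiant_exposure: float) -> StimulusParadigm:
    """Build one of the two standard INS paradigms.

    Parameters
    ----------
    kind
        ``"multi_train"`` or ``"long_train"``.
    radiant_exposure
        Per-pulse radiant exposure at the fiber tip, J/cm² (0 for sham).
    """
    if kind == "multi_train":
        return StimulusParadigm(
            pulse_width_ms=0.25,
            pulse_rate_hz=200.0,
            train_duration_s=0.5,
            n_trains=6,
            train_interval_s=2.5,
            trial_length_s=60.0,
            baseline_length_s=10.0,
            radiant_exposure=radiant_exposure,
            label="multi_train",
        )
    if kind == "long_train":
        return StimulusParadigm(
            pulse_width_ms=0.25,
            pulse_rate_hz=200.0,
            train_duration_s=2.0,
            n_trains=1,
            train_interval_s=0.0,
            trial_length_s=30.0,
            baseline_length_s=3.0,
            radiant_exposure=radiant_exposure,
            label="long_train",
        )
    raise ParadigmError(f"unknown paradigm kind: {kind!r}")
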