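"""Excitatory/inhibitory weighted population response.

Cortex holds roughly 80% excitatory and 20% inhibitory neurons, so the
expected population calcium time course under stimulation is approximated by
the convex combination ``0.8 × excitatory mean + 0.2 × inhibitory mean`` of
the two cohort grand-mean ΔF/F0 curves at a chosen radiant exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import DffTrace

__all__ = ["PopulationWeights", "PopulationCurve", "population_sum"]


@dataclass(frozen=True)
class PopulationWeights:
    """Cohort mixing weights; must be non-negative and sum to 1."""

    w_excitatory: float = 0.8
    w_inhibitory: float = 0.2

    def __post_init__(self) -> None:
        if self.w_excitatory < 0 or self.w_inhibitory < 0:
            raise ValueError("weights must be >= 0")
        if abs(self.w_excitatory + self.w_inhibitory - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class PopulationCurve:
    """Weighted population mean with its two component curves."""

    values: np.ndarray
    sampling_rate: float
    excitatory: np.ndarray
    inhibitory: np.ndarray
    weights: PopulationWeights


def population_sum(
    exc_mean: DffTrace,
    inh_mean: DffTrace,
    weights: PopulationWeights | None = None,
) -> PopulationCurve:
    """Pointwise weighted sum of the two cohort mean ΔF/F0 curves."""
    weights = weights or PopulationWeights()
    if exc_mean.values.size != inh_mean.values.size:
        raise ValueError("component curves must have the same length")
    if exc_mean.sampling_rate != inh_mean.sampling_rate:
        raise ValueError("component curves must share a sampling rate")
    values = weights.w_excitatory * exc_mean.values + weights.w_inhibitory * inh_mean.values
    return PopulationCurve(
        values=values,
        sampling_rate=exc_mean.sampling_rate,
        excitatory=exc_mean.values.copy(),
        inhibitory=inh_mean.values.copy(),
        weights=weights,
    )
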