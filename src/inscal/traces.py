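"""Raw fluorescence → smoothed, trial-averaged ΔF/F0.

ΔF/F0 = (F − F0)/F0 with F0 the mean fluorescence over the pre-stimulus
baseline window.  Smoothing uses a causal scalar Kalman filter (constant-level
state-space model); it is intended for display curves, while the response
metrics operate on raw ΔF/F0 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DffTrace",
    "BaselineError",
    "compute_dff",
    "kalman_smooth",
    "trial_average",
    "extract_roi_traces",
]


class BaselineError(ValueError):
    """Raised when the baseline window is invalid or F0 is non-positive."""


@dataclass
class DffTrace:
    """A ΔF/F0 time series with its sampling rate and baseline bookkeeping."""

    values: np.ndarray
    sampling_rate: float
    baseline_window: tuple[float, float]
    f0: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.f0 <= 0:
            raise BaselineError(f"f0 must be > 0, got {self.f0}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("ΔF/F0 values must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        """Values within the half-open time window [start, end)."""
        i0 = int(round(window[0] * self.sampling_rate))
        i1 = int(round(window[1] * self.sampling_rate))
        if not 0 <= i0 < i1 <= self.values.size:
            raise ValueError(f"window {window} outside trace of {self.values.size} samples")
        return self.values[i0:i1]


def compute_dff(
    trace: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float],
) -> DffTrace:
    """Convert a raw fluorescence trace to ΔF/F0.

    F0 is the mean of ``trace`` over ``baseline_window`` (seconds, half-open);
    the window must lie inside the trace.  A non-positive F0 is rejected
    rather than silently producing huge ratios.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(baseline_window[0] * sampling_rate))
    i1 = int(round(baseline_window[1] * sampling_rate))
    if not 0 <= i0 < i1 <= trace.size:
        raise BaselineError(f"baseline window {baseline_window} outside trace")
    f0 = float(trace[i0:i1].mean())
    if f0 <= 0:
        raise BaselineError(f"baseline fluorescence F0 = {f0} is not positive")
    return DffTrace(
        values=(trace - f0) / f0,
        sampling_rate=sampling_rate,
        baseline_window=baseline_window,
        f0=f0,
    )


def kalman_smooth(
    trace: DffTrace,
    gain: float = 0.5,
    process_noise: float = 0.05,
) -> DffTrace:
    """Causal scalar Kalman smoothing of a ΔF/F0 trace.

    A constant-level state-space model with unit measurement-noise variance:
    ``estimate_t = estimate_{t-1} + k_t (obs_t − estimate_{t-1})`` where the
    Kalman gain ``k_t`` follows the standard scalar recursion with process
    noise ``process_noise``, starting from ``gain``.  The first output equals
    the first input; ``gain = 1`` passes the input through unchanged.
    """
    if not 0 < gain <= 1:
        raise ValueError("gain must lie in (0, 1]")
    if process_noise < 0:
        raise ValueError("process_noise must be >= 0")
    obs = trace.values
    if gain == 1.0 or obs.size == 0:
        return replace(trace, values=obs.copy())
    out = np.empty_like(obs)
    out[0] = obs[0]
    # unit R; choose predicted error variance so the first gain equals `gain`
    p_pred = gain / (1.0 - gain)
    x = obs[0]
    for t in range(1, obs.size):
        k = p_pred / (p_pred + 1.0)
        x = x + k * (obs[t] - x)
        p_pred = (1.0 - k) * p_pred + process_noise
        out[t] = x
    return replace(trace, values=out)


def trial_average(traces: list[DffTrace]) -> DffTrace:
    """Pointwise mean of repeated-trial ΔF/F0 traces."""
    if not traces:
        raise ValueError("cannot average an empty list of traces")
    n = traces[0].values.size
    fs = traces[0].sampling_rate
    for t in traces[1:]:
        if t.values.size != n:
            raise ValueError("all traces must have the same length")
        if t.sampling_rate != fs:
            raise ValueError("all traces must share a sampling rate")
    mean = np.mean([t.values for t in traces], axis=0)
    return DffTrace(
        values=mean,
        sampling_rate=fs,
        baseline_window=traces[0].baseline_window,
        f0=float(np.mean([t.f0 for t in traces])),
    )


def extract_roi_traces(stack: np.ndarray, mask: np.ndarray) -> dict[int, np.ndarray]:
    """Mean-pixel fluorescence traces from a registered stack and a label mask.

    ``stack`` is [frame, y, x]; ``mask`` is an integer label image where label
    n > 0 marks ROI n and 0 is background.  Returns ``{label: trace}`` with
    one sample per frame.
    """
    stack = np.asarray(stack)
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("ROI mask must be an integer label image")
    if stack.ndim != 3 or mask.shape != stack.shape[1:]:
        raise ValueError("stack must be [frame, y, x] matching the mask shape")
    out: dict[int, np.ndarray] = {}
    for label in np.unique(mask):
        if label == 0:
            continue
        sel = mask == label
        out[int(label)] = stack[:, sel].mean(axis=1).astype(float)
    return out
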