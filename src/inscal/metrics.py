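"""Response statistics for INS calcium data.

The core quantities, computed per neuron and per radiant exposure from the
trial-averaged ΔF/F0 curve:

* **correlation index** — Pearson correlation, over the stimulation window,
  between the neuron's trial-averaged response and a cohort reference curve
  (the cohort mean response at the top radiant exposure, 0.76 J/cm²).
  A neuron is classified *positive* when the index exceeds +0.2 and
  *negative* below −0.2; otherwise unclassified.
* **amplitude** — the mean of the six per-train peak-to-peak excursions
  (p1..p6), signed by the correlation index.
* **AUC (3–10 s)** — for the long-train paradigm, total area of
  above-baseline peaks in the 3–10 s window, ignoring peaks smaller than 10%
  of the min-to-max range.

Plus cohort summaries: classification fractions per intensity, the linear
intensity-dependence fit of the mean correlation index, and rank tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import StimulusParadigm
from .traces import DffTrace

__all__ = [
    "ReferenceCurve",
    "ResponseProfile",
    "ClassifierConfig",
    "build_reference",
    "correlation_index",
    "classify",
    "peak_amplitude",
    "auc_3_10",
    "classification_fractions",
    "intensity_fit",
    "FitResult",
    "rank_compare",
    "count_unique_labeled",
    "select_top_fraction",
    "round_half_away",
]

#: Stimulation-epoch analysis window of the multi-train paradigm, seconds.
DEFAULT_ANALYSIS_WINDOW: tuple[float, float] = (10.0, 28.0)


@dataclass
class ClassifierConfig:
    """Correlation-threshold classifier settings (±0.2 defaults)."""

    threshold_pos: float = 0.2
    threshold_neg: float = -0.2
    analysis_window: tuple[float, float] = DEFAULT_ANALYSIS_WINDOW

    def __post_init__(self) -> None:
        if not self.threshold_neg < 0 < self.threshold_pos:
            raise ValueError("need threshold_neg < 0 < threshold_pos")


@dataclass
class ReferenceCurve:
    """Cohort-mean ΔF/F0 over the stimulation window at one intensity."""

    values: np.ndarray
    sampling_rate: float
    window: tuple[float, float]
    source_intensity: float
    n_contributing: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2 or float(np.std(self.values)) == 0.0:
            raise ValueError("reference curve must have nonzero variance")


@dataclass
class ResponseProfile:
    """Per-neuron, per-intensity response statistics."""

    neuron_id: int
    intensity: float
    correlation_value: float
    label: str
    amplitude: float
    peaks: np.ndarray = field(default_factory=lambda: np.full(6, np.nan))
    auc_3_10: float = float("nan")


def build_reference(
    cell_averages: list[DffTrace],
    window: tuple[float, float] = DEFAULT_ANALYSIS_WINDOW,
    source_intensity: float = 0.76,
) -> ReferenceCurve:
    """Mean response over contributing neurons, restricted to ``window``.

    ``cell_averages`` are the trial-averaged ΔF/F0 curves of every
    contributing neuron at the reference intensity (no pre-selection).
    """
    if not cell_averages:
        raise ValueError("cannot build a reference from no neurons")
    segs = [t.window_slice(window) for t in cell_averages]
    n = segs[0].size
    if any(s.size != n for s in segs):
        raise ValueError("all cell averages must cover the window equally")
    mean = np.mean(segs, axis=0)
    return ReferenceCurve(
        values=mean,
        sampling_rate=cell_averages[0].sampling_rate,
        window=window,
        source_intensity=source_intensity,
        n_contributing=len(cell_averages),
    )


def correlation_index(
    cell_avg: DffTrace,
    reference: ReferenceCurve,
    window: tuple[float, float] | None = None,
) -> float:
    """Pearson correlation of a cell's averaged response with the reference.

    Returns NaN (classified "none" downstream) when either windowed series
    has zero variance, rather than a silent zero.
    """
    window = reference.window if window is None else window
    x = cell_avg.window_slice(window)
    y = reference.values
    if x.size != y.size:
        raise ValueError("window sample counts of cell and reference differ")
    if float(np.std(x)) == 0.0 or float(np.std(y)) == 0.0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def classify(correlation_value: float, config: ClassifierConfig | None = None) -> str:
    """Threshold classification: "positive", "negative", or "none".

    Strict inequalities: a value exactly at a threshold is "none"; an
    undefined (NaN) correlation is "none".
    """
    config = config or ClassifierConfig()
    if correlation_value is None or math.isnan(correlation_value):
        return "none"
    if correlation_value > config.threshold_pos:
        return "positive"
    if correlation_value < config.threshold_neg:
        return "negative"
    return "none"


def peak_amplitude(
    cell_avg: DffTrace,
    paradigm: StimulusParadigm,
    correlation_value: float,
) -> tuple[float, np.ndarray]:
    """Signed mean peak-to-peak amplitude over the six train epochs.

    Each epoch runs from one train onset to the next (the last epoch has the
    same duration), partitioning the 18 s stimulation period into six 3 s
    epochs; p_i is the max − min ΔF/F0 excursion within epoch i.  The mean of
    p1..p6 takes the sign of the correlation index, so negative-going
    (inhibitory-like) responders get negative amplitudes.
    """
    if paradigm.n_trains != 6:
        raise ValueError("peak amplitude is defined for the six-train paradigm")
    fs = cell_avg.sampling_rate
    period = paradigm.train_period_s
    peaks = np.empty(6)
    for i, onset in enumerate(paradigm.train_onsets_s):
        seg = cell_avg.window_slice((onset, onset + period))
        peaks[i] = float(seg.max() - seg.min())
    if correlation_value is None or math.isnan(correlation_value):
        sign = 0.0
    else:
        sign = math.copysign(1.0, correlation_value) if correlation_value != 0 else 0.0
    return float(peaks.mean() * sign), peaks


def auc_3_10(
    cell_avg: DffTrace,
    window: tuple[float, float] = (3.0, 10.0),
    min_peak_fraction: float = 0.10,
) -> float:
    """Total above-zero peak area in the 3–10 s window (long-train paradigm).

    Maximal contiguous above-zero segments are found within the window;
    segments whose maximum falls below ``global_min + min_peak_fraction ×
    (global_max − global_min)`` (range computed over the window) are ignored
    as too small to count.  Areas are trapezoidal, with the zero crossings of
    each retained segment linearly interpolated.  Units: ΔF/F0 × s.
    """
    fs = cell_avg.sampling_rate
    if cell_avg.values.size < int(round(window[1] * fs)):
        raise ValueError(f"trace must cover the full {window} window")
    y = cell_avg.window_slice(window)
    t = np.arange(y.size) / fs + window[0]
    gmin, gmax = float(y.min()), float(y.max())
    if gmax <= 0:
        return 0.0
    height_floor = gmin + min_peak_fraction * (gmax - gmin)

    above = y > 0
    # segment boundaries in sample indices
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [e + 1 for e in edges if not above[e]]
    ends = [e + 1 for e in edges if above[e]]
    if above[-1]:
        ends.append(y.size)

    total = 0.0
    for s, e in zip(starts, ends):
        seg_y, seg_t = y[s:e], t[s:e]
        if float(seg_y.max()) < height_floor:
            continue
        # interpolated zero crossings at the segment borders
        ys, ts = list(seg_y), list(seg_t)
        if s > 0:
            y0, y1 = y[s - 1], y[s]
            frac = -y0 / (y1 - y0)
            ts.insert(0, t[s - 1] + frac / fs)
            ys.insert(0, 0.0)
        if e < y.size:
            y0, y1 = y[e - 1], y[e]
            frac = -y0 / (y1 - y0)
            ts.append(t[e - 1] + frac / fs)
            ys.append(0.0)
        total += float(np.trapezoid(ys, ts))
    return total


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (printing convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def classification_fractions(
    profiles: list[ResponseProfile] | pd.DataFrame,
) -> pd.DataFrame:
    """Counts and percentages of positive/negative responders per intensity.

    Percentages are ``100 × n / n_total`` rounded to one decimal, ties away
    from zero.
    """
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        if not profiles:
            raise ValueError("no profiles given")
        df = pd.DataFrame(
            {
                "intensity": [p.intensity for p in profiles],
                "label": [p.label for p in profiles],
            }
        )
    if df.empty:
        raise ValueError("no profiles given")
    rows = []
    for intensity, grp in df.groupby("intensity", sort=True):
        n_total = len(grp)
        n_pos = int((grp["label"] == "positive").sum())
        n_neg = int((grp["label"] == "negative").sum())
        rows.append(
            {
                "intensity": float(intensity),
                "n_pos": n_pos,
                "n_neg": n_neg,
                "n_none": n_total - n_pos - n_neg,
                "n_total": n_total,
                "pct_pos": round_half_away(100.0 * n_pos / n_total),
                "pct_neg": round_half_away(100.0 * n_neg / n_total),
                "pct_none": round_half_away(100.0 * (n_total - n_pos - n_neg) / n_total),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def intensity_fit(points: list[tuple[float, float]]) -> FitResult:
    """Ordinary least-squares line through (radiant exposure, mean correlation).

    Returns slope, intercept, R², and the two-sided p-value of the slope.
    """
    if len(points) < 3:
        raise ValueError("intensity fit needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if np.isnan(res.rvalue):  # constant y: slope 0, no explained variance
        r2 = 0.0
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=float(res.pvalue),
    )


def rank_compare(a, b, paired: bool) -> float:
    """Two-sided rank-test p-value: Wilcoxon signed-rank (paired) or
    Mann–Whitney U (unpaired).

    Exact null distributions are used for small samples (n ≤ 25, no ties);
    otherwise the normal approximation with tie correction.  Degenerate
    inputs — all paired differences zero, or all values tied across both
    groups — are undefined: identical paired samples return p = 1 (no
    evidence of a shift), fully tied unpaired samples return NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length samples")
        d = a - b
        if np.all(d == 0):
            return 1.0
        exact_ok = (
            a.size <= 25
            and np.all(d != 0)
            and np.unique(np.abs(d)).size == d.size
        )
        method = "exact" if exact_ok else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
        return float(res.pvalue)
    if np.unique(np.concatenate([a, b])).size == 1:
        return float("nan")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def count_unique_labeled(n_a: int, n_b: int, n_colabeled: int) -> int:
    """Unique neurons across two labels by inclusion–exclusion."""
    if min(n_a, n_b, n_colabeled) < 0 or n_colabeled > min(n_a, n_b):
        raise ValueError("invalid co-labeling counts")
    return n_a + n_b - n_colabeled


def select_top_fraction(values, fraction: float = 0.10) -> np.ndarray:
    """Indices of the top ``fraction`` of ``values`` (ceiling count), sorted
    by descending value.  With 335 neurons the top decile has 34 members."""
    values = np.asarray(values, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * values.size)
    order = np.argsort(-values, kind="stable")
    return order[:k]
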