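"""Figure helpers: response matrices and population-sum curves."""

from __future__ import annotations

import numpy as np

from .population import PopulationCurve


def plot_response_matrix(profiles, avgs, intensity, window=(0.0, 60.0), ax=None):
    """Pseudo-coloured matrix of trial-averaged ΔF/F0 per neuron at one
    intensity, rows sorted by correlation index (strongest responders on
    top)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = profiles[profiles["intensity"] == intensity].sort_values(
        "correlation_value", ascending=False
    )
    rows = []
    for i in sub.index:
        nid = sub.loc[i, "neuron_id"]
        rows.append(avgs[(int(nid), float(intensity))].window_slice(window))
    mat = np.vstack(rows)
    im = ax.imshow(mat, aspect="auto", cmap="viridis", interpolation="nearest",
                   extent=[window[0], window[1], mat.shape[0], 0])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron (sorted by correlation)")
    plt.colorbar(im, ax=ax, label="ΔF/F0")
    return ax


def plot_population_curve(curve: PopulationCurve, stim_window=None, ax=None):
    """Three-trace layout: excitatory, inhibitory, and weighted sum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = np.arange(curve.values.size) / curve.sampling_rate
    ax.plot(t, curve.excitatory, color="purple", lw=1,
            label=f"excitatory ({curve.weights.w_excitatory:.0%})")
    ax.plot(t, curve.inhibitory, color="green", lw=1,
            label=f"inhibitory ({curve.weights.w_inhibitory:.0%})")
    ax.plot(t, curve.values, color="black", lw=1.5, label="population sum")
    if stim_window is not None:
        ax.axvspan(*stim_window, color="pink", alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ΔF/F0")
    ax.legend(frameon=False, fontsize=8)
    return ax
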