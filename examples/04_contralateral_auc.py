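"""Long-train paradigm and the 3–10 s peak-area analysis.

Distal (contralateral) responses are probed with a single 2 s, 400-pulse
train and quantified by the area under the above-baseline peaks of the
trial-averaged ΔF/F0 between 3 and 10 s (peaks below 10% of the min-to-max
range are ignored).  The strongest decile of responders is compared against
sham trials with a paired rank test.
"""

import numpy as np

from inscal import SimulationConfig, rank_compare, select_top_fraction, simulate_dataset
from inscal.pipeline import process_dataset

config = SimulationConfig(
    paradigm_kind="long_train",
    n_excitatory=100,
    responsive_fraction=0.4,
    intensities=(0.0, 0.46),  # sham and stimulated trials
    trials_per_intensity=6,
    response_gain=0.4,
)
dataset = simulate_dataset(config, seed=9)
profiles, _ = process_dataset(dataset)

ins = profiles[profiles.intensity == 0.46].set_index("neuron_id")["auc_3_10"]
sham = profiles[profiles.intensity == 0.0].set_index("neuron_id")["auc_3_10"]

top = select_top_fraction(ins.to_numpy(), 0.10)
p = rank_compare(ins.to_numpy()[top], sham.to_numpy()[top], paired=True)

print(f"{len(ins)} neurons; top decile = {top.size} neurons")
print(f"mean 3-10 s peak area, top decile:  stimulated {ins.to_numpy()[top].mean():.2f}, "
      f"sham {sham.to_numpy()[top].mean():.2f} (ΔF/F0 x s)")
print(f"paired Wilcoxon p = {p:.2e}")
print("\na larger stimulated area with a small p-value indicates a delayed, "
      "seconds-long activation beyond spontaneous activity.")
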