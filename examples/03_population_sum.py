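"""80/20 excitatory/inhibitory population response.

Simulates a mixed cohort in which excitatory neurons respond positive-going
and inhibitory neurons negative-going, then forms the weighted population
time course (80% excitatory, 20% inhibitory — the standard cortical ratio)
at 0.42 J/cm².
"""

import numpy as np

from inscal import PopulationWeights, SimulationConfig, population_sum, simulate_dataset
from inscal.pipeline import cell_averages
from inscal.traces import trial_average

config = SimulationConfig(n_excitatory=40, n_inhibitory=10)
dataset = simulate_dataset(config, seed=3)
avgs = cell_averages(dataset)

q = 0.42
exc_idx = [i for i, n in enumerate(dataset.neurons) if n.cell_class == "excitatory"]
inh_idx = [i for i, n in enumerate(dataset.neurons) if n.cell_class == "inhibitory"]
exc = trial_average([avgs[(i, q)] for i in exc_idx])
inh = trial_average([avgs[(i, q)] for i in inh_idx])

curve = population_sum(exc, inh, PopulationWeights(0.8, 0.2))

stim = dataset.paradigm.stim_window_s
fs = curve.sampling_rate
sl = slice(int(stim[0] * fs), int(stim[1] * fs))
print(f"at {q} J/cm^2, during the 18 s stimulation epoch:")
print(f"  excitatory cohort mean peak ΔF/F0: {exc.values[sl].max():+.3f}")
print(f"  inhibitory cohort mean trough:     {inh.values[sl].min():+.3f}")
print(f"  80/20 population sum peak:         {curve.values[sl].max():+.3f}")
print("\nthe weighted sum stays positive and pulse-train-locked: the "
      "excitatory majority dominates the population calcium signal even "
      "though the inhibitory cohort deflects negative.")
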