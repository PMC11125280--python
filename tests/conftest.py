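import numpy as np
import pytest

from inscal.paradigm import make_paradigm
from inscal.synthetic import NeuronSpec, SimulationConfig, simulate_dataset, simulate_trial
from inscal.traces import DffTrace, compute_dff

FS = 30.0


def make_neuron(**overrides) -> NeuronSpec:
    base = dict(
        id=0,
        cell_class="excitatory",
        position=(100.0, 100.0, 20.0),
        responsive=True,
        response_gain=0.6,
        response_sign=1,
        spontaneous_rate=0.0,
        noise_sigma=0.0,
        artifact_depth=0.0,
    )
    base.update(overrides)
    return NeuronSpec(**base)


@pytest.fixture(scope="session")
def multi_paradigm():
    return make_paradigm("multi_train", 0.76)


@pytest.fixture(scope="session")
def noiseless_avg(multi_paradigm):
    """Trial-averaged ΔF/F0 of a deterministic high-gain responder."""
    trace = simulate_trial(make_neuron(), multi_paradigm, FS, seed=0)
    return compute_dff(trace, FS, (0.0, 10.0))


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(
        n_excitatory=12,
        intensities=(0.0, 0.42, 0.76),
        trials_per_intensity=3,
        noise_sigma=0.03,
        spontaneous_rate=0.0,
        gain_jitter=0.0,
    )
    return simulate_dataset(cfg, seed=11)


def dff_from(values, fs=FS, f0=100.0):
    return DffTrace(values=np.asarray(values, float), sampling_rate=fs,
                    baseline_window=(0.0, 1.0), f0=f0)
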