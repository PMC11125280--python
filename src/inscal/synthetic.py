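"""Synthetic two-photon calcium datasets with INS-locked responses.

The generator emulates the statistical structure the downstream analysis
assumes: raw somatic fluorescence sampled at ~30 Hz, a pre-stimulus baseline,
pulse-train-locked calcium transients whose amplitude grows with radiant
exposure (positive in excitatory cells, negative-going in inhibitory cells),
an optional fluoro-thermal artifact (a fluorescence dip confined to each
pulse train), spontaneous transients, and additive Gaussian noise.

Ground-truth neuron specifications are kept alongside the traces so that
classification can be scored against the generating labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .paradigm import StimulusParadigm, make_paradigm

__all__ = [
    "NeuronSpec",
    "TraceSet",
    "SimulationConfig",
    "calcium_kernel",
    "amplitude_law",
    "sample_population",
    "simulate_trial",
    "simulate_dataset",
]

#: Default radiant exposures, J/cm² per pulse (0 is the sham condition).
DEFAULT_INTENSITIES: tuple[float, ...] = (0.0, 0.16, 0.29, 0.42, 0.50, 0.59, 0.68, 0.76)


@dataclass
class NeuronSpec:
    """Generative parameters of one simulated neuron.

    ``response_gain`` is the ΔF/F0 response amplitude per J/cm² of radiant
    exposure above threshold; ``response_sign`` is +1 for positive-going
    (excitatory-like) and −1 for negative-going (inhibitory-like) responses.
    ``artifact_depth`` is the fluorescence dip (ΔF/F0 units) during each pulse
    train at the reference exposure, modelling the thermal effect seen in
    dead-animal controls.
    """

    id: int
    cell_class: str
    position: tuple[float, float, float]
    responsive: bool
    response_gain: float
    response_sign: int
    spontaneous_rate: float
    noise_sigma: float
    artifact_depth: float

    def __post_init__(self) -> None:
        if self.cell_class not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown cell_class: {self.cell_class!r}")
        if self.response_sign not in (-1, 1):
            raise ValueError("response_sign must be -1 or +1")
        if self.cell_class == "excitatory" and self.response_sign != 1:
            raise ValueError("excitatory neurons must have response_sign = +1")
        if self.noise_sigma < 0 or self.spontaneous_rate < 0:
            raise ValueError("noise_sigma and spontaneous_rate must be >= 0")


@dataclass
class TraceSet:
    """Raw fluorescence traces: array [neuron, trial, sample] plus metadata.

    ``intensity_order`` gives the radiant exposure delivered on each trial, in
    the (randomised) order the trials were run.
    """

    traces: np.ndarray
    sampling_rate: float
    paradigm: StimulusParadigm
    neurons: list[NeuronSpec]
    intensity_order: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.intensity_order = np.asarray(self.intensity_order, dtype=float)
        if self.traces.ndim != 3:
            raise ValueError("traces must be [neuron, trial, sample]")
        n_expected = int(round(self.paradigm.trial_length_s * self.sampling_rate))
        if self.traces.shape[2] != n_expected:
            raise ValueError(
                f"trace length {self.traces.shape[2]} != "
                f"round(trial_length x sampling_rate) = {n_expected}"
            )
        if self.traces.shape[1] != self.intensity_order.size:
            raise ValueError("intensity_order length must match trial count")
        if self.traces.size and not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.traces.size and self.traces.min() <= 0:
            raise ValueError("raw fluorescence must be strictly positive")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_trials(self) -> int:
        return self.traces.shape[1]

    @property
    def intensities(self) -> np.ndarray:
        """Sorted unique radiant exposures present in the trial order."""
        return np.unique(self.intensity_order)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset generator, with study defaults.

    Defaults reproduce the multi-train experiment layout: eight radiant
    exposures (including sham 0), six trials per exposure in randomised
    order, 30 Hz sampling.
    """

    paradigm_kind: str = "multi_train"
    intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    trials_per_intensity: int = 6
    sampling_rate: float = 30.0
    n_excitatory: int = 100
    n_inhibitory: int = 0
    responsive_fraction: float = 1.0
    field_um: tuple[float, float, float] = (500.0, 500.0, 50.0)
    f0: float = 100.0
    response_gain: float = 0.6
    gain_jitter: float = 0.2
    amplitude_threshold: float = 0.1
    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.5
    noise_sigma: float = 0.05
    spontaneous_rate: float = 0.02
    spontaneous_amplitude: float = 0.4
    artifact_depth: float = 0.0
    artifact_reference_exposure: float = 0.76

    def __post_init__(self) -> None:
        if len(self.intensities) == 0:
            raise ValueError("intensity list must not be empty")
        if self.trials_per_intensity < 1:
            raise ValueError("trials_per_intensity must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intensities"] = list(d["intensities"])
        d["field_um"] = list(d["field_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "intensities" in d:
            d["intensities"] = tuple(d["intensities"])
        if "field_um" in d:
            d["field_um"] = tuple(d["field_um"])
        return cls(**d)


def calcium_kernel(
    sampling_rate: float,
    rise_s: float = 0.18,
    decay_s: float = 1.5,
    duration_s: float = 8.0,
) -> np.ndarray:
    """Difference-of-exponentials calcium impulse response, peak-normalised.

    ``k(t) = exp(-t/decay) - exp(-t/rise)`` scaled to unit peak — a standard
    fast-rise / slow-decay surrogate for a slow indicator such as GCaMP6s.
    """
    if not 0 < rise_s < decay_s:
        raise ValueError("need 0 < rise < decay")
    t = np.arange(int(round(duration_s * sampling_rate))) / sampling_rate
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def amplitude_law(radiant_exposure: float, gain: float, threshold: float = 0.1) -> float:
    """Response ΔF/F0 amplitude vs radiant exposure: linear above threshold.

    Monotone non-decreasing in exposure and exactly 0 at 0 J/cm².
    """
    return gain * max(0.0, radiant_exposure - threshold)


def sample_population(
    n_excitatory: int,
    n_inhibitory: int,
    responsive_fraction: float,
    field_um: tuple[float, float, float] = (500.0, 500.0, 50.0),
    seed: int | np.random.SeedSequence = 0,
    *,
    response_gain: float = 0.6,
    gain_jitter: float = 0.2,
    noise_sigma: float = 0.05,
    spontaneous_rate: float = 0.02,
    artifact_depth: float = 0.0,
) -> list[NeuronSpec]:
    """Draw a cohort of neuron specifications.

    Positions are uniform over ``field_um``; each neuron is responsive with
    probability ``responsive_fraction`` independently.  Per-neuron gains get
    multiplicative log-normal jitter (sigma ``gain_jitter``) so the cohort is
    heterogeneous.  Inhibitory neurons respond negative-going (sign −1).
    """
    if n_excitatory < 0 or n_inhibitory < 0:
        raise ValueError("neuron counts must be >= 0")
    if not 0 <= responsive_fraction <= 1:
        raise ValueError("responsive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    neurons: list[NeuronSpec] = []
    classes = ["excitatory"] * n_excitatory + ["inhibitory"] * n_inhibitory
    for i, cls in enumerate(classes):
        pos = tuple(rng.uniform(0, e) for e in field_um)
        responsive = bool(rng.random() < responsive_fraction)
        gain = response_gain * float(rng.lognormal(0.0, gain_jitter)) if gain_jitter else response_gain
        neurons.append(
            NeuronSpec(
                id=i,
                cell_class=cls,
                position=pos,
                responsive=responsive,
                response_gain=gain,
                response_sign=1 if cls == "excitatory" else -1,
                spontaneous_rate=spontaneous_rate,
                noise_sigma=noise_sigma,
                artifact_depth=artifact_depth,
            )
        )
    return neurons


def simulate_trial(
    neuron: NeuronSpec,
    paradigm: StimulusParadigm,
    sampling_rate: float,
    seed: int | np.random.SeedSequence,
    *,
    f0: float = 100.0,
    kernel: np.ndarray | None = None,
    kernel_rise_s: float = 0.18,
    kernel_decay_s: float = 1.5,
    amplitude_threshold: float = 0.1,
    spontaneous_amplitude: float = 0.4,
    artifact_reference_exposure: float = 0.76,
) -> np.ndarray:
    """Simulate one raw-fluorescence trial for one neuron.

    The trace is ``f0 * (1 + dff)`` where ``dff`` sums (i) the pulse-train
    response — signed amplitude from :func:`amplitude_law` convolved with the
    calcium kernel at each train onset, (ii) a negative boxcar artifact during
    each train scaling linearly with exposure, (iii) spontaneous transients
    from a homogeneous Poisson event process, and (iv) Gaussian noise.
    Deterministic given ``seed``.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(paradigm.trial_length_s * sampling_rate))
    if kernel is None:
        kernel = calcium_kernel(sampling_rate, kernel_rise_s, kernel_decay_s)
    dff = np.zeros(n)
    onset_idx = np.round(paradigm.train_onsets_s * sampling_rate).astype(int)
    q = paradigm.radiant_exposure

    amp = amplitude_law(q, neuron.response_gain, amplitude_threshold)
    if neuron.responsive and amp > 0:
        impulses = np.zeros(n)
        impulses[onset_idx[onset_idx < n]] = 1.0
        dff += neuron.response_sign * amp * np.convolve(impulses, kernel)[:n]

    if neuron.artifact_depth > 0 and q > 0:
        depth = neuron.artifact_depth * q / artifact_reference_exposure
        dur = int(round(paradigm.train_duration_s * sampling_rate))
        for i0 in onset_idx:
            dff[i0 : min(i0 + dur, n)] -= depth

    if neuron.spontaneous_rate > 0:
        n_ev = rng.poisson(neuron.spontaneous_rate * paradigm.trial_length_s)
        if n_ev:
            ev_idx = rng.integers(0, n, n_ev)
            ev_amp = rng.exponential(spontaneous_amplitude, n_ev)
            impulses = np.zeros(n)
            np.add.at(impulses, ev_idx, ev_amp)
            dff += np.convolve(impulses, kernel)[:n]

    if neuron.noise_sigma > 0:
        dff += rng.normal(0.0, neuron.noise_sigma, n)

    return f0 * (1.0 + dff)


def simulate_dataset(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> TraceSet:
    """Simulate a full dataset under ``config``.

    Trial order is a seeded random permutation over the configured radiant
    exposures (each repeated ``trials_per_intensity`` times), mirroring the
    randomised presentation of laser powers.  All randomness derives from one
    :class:`numpy.random.SeedSequence` split into independent streams for the
    population draw, the trial order, and each (neuron, trial) trace, so the
    output is bit-identical for identical ``(config, seed)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_ss, order_ss, trace_ss = ss.spawn(3)

    neurons = sample_population(
        config.n_excitatory,
        config.n_inhibitory,
        config.responsive_fraction,
        config.field_um,
        seed=pop_ss,
        response_gain=config.response_gain,
        gain_jitter=config.gain_jitter,
        noise_sigma=config.noise_sigma,
        spontaneous_rate=config.spontaneous_rate,
        artifact_depth=config.artifact_depth,
    )

    exposures = np.repeat(np.asarray(config.intensities, dtype=float), config.trials_per_intensity)
    order_rng = np.random.default_rng(order_ss)
    exposures = exposures[order_rng.permutation(exposures.size)]

    base = make_paradigm(config.paradigm_kind, 0.0)
    paradigms = {q: base.at_exposure(q) for q in np.unique(exposures)}
    kernel = calcium_kernel(config.sampling_rate, config.kernel_rise_s, config.kernel_decay_s)

    n_samples = int(round(base.trial_length_s * config.sampling_rate))
    traces = np.empty((len(neurons), exposures.size, n_samples))
    children = trace_ss.spawn(len(neurons) * exposures.size)
    k = 0
    for i, neuron in enumerate(neurons):
        for j, q in enumerate(exposures):
            traces[i, j] = simulate_trial(
                neuron,
                paradigms[q],
                config.sampling_rate,
                children[k],
                f0=config.f0,
                kernel=kernel,
                amplitude_threshold=config.amplitude_threshold,
                spontaneous_amplitude=config.spontaneous_amplitude,
                artifact_reference_exposure=config.artifact_reference_exposure,
            )
            k += 1

    return TraceSet(
        traces=traces,
        sampling_rate=config.sampling_rate,
        paradigm=base,
        neurons=neurons,
        intensity_order=exposures,
    )
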