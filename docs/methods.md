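# Methods

`inscal` re-implements, as a tested pipeline, the analysis chain used to
characterise single-neuron calcium responses to pulsed infrared neural
stimulation (INS, 1875 nm): synthetic two-photon trace generation, ΔF/F0
processing, correlation-index classification, Monte Carlo modelling of the
infrared light field, and the excitatory/inhibitory population sum.  This
note records the models, the defaults and why they were chosen, and what the
synthetic validation does and does not establish.

## Stimulation paradigms

Two trial structures are built in:

* **multi-train** — 60 s trial: 10 s baseline; six 0.5 s pulse trains
  (0.25 ms pulses at 200 Hz, 100 pulses/train) at 2.5 s gaps, i.e. a 3 s
  onset-to-onset period filling an 18 s stimulation epoch; 32 s recovery.
* **long-train** — 30 s trial: 3 s baseline; one 2 s train (400 pulses);
  25 s recovery.  Used for distal-response (contralateral) measurements.

Radiant exposure is the per-pulse energy density at the fiber tip (J/cm²);
the default intensity ladder is 0 (sham), 0.16, 0.29, 0.42, 0.50, 0.59,
0.68, 0.76 J/cm², six trials per intensity, presented in seeded random
order.  Intervals are half-open `[start, end)` in seconds from trial start.

## Synthetic data generator

Traces are synthesised at the trace level (not pixel level) as
`F = F0 · (1 + ΔF/F0)`, with `F0 = 100` a.u. and ΔF/F0 the sum of:

* **Stimulus response.**  A unit impulse at each train onset convolved with
  a peak-normalised difference-of-exponentials kernel
  (`exp(−t/τ_decay) − exp(−t/τ_rise)`, defaults τ_rise = 0.18 s,
  τ_decay = 1.5 s — a generic slow-indicator surrogate; the true GCaMP6s
  kinetics are not pinned by any measurement here and both constants are
  parameters).  The impulse amplitude follows a **linear-above-threshold
  law** `A(Q) = gain · max(0, Q − Q_thr)` with threshold 0.1 J/cm² and
  default gain 0.6 ΔF/F0 per J/cm²; the only property the analysis relies
  on is that A is monotone non-decreasing and zero at zero exposure.
  Per-neuron gains carry log-normal jitter (σ = 0.2) so cohorts are
  heterogeneous.  Excitatory neurons respond with sign +1; inhibitory
  neurons default to −1 (negative-going), the phenomenology the classifier
  must detect.
* **Thermal artifact.**  An optional negative boxcar during each pulse train
  whose depth scales linearly with exposure (normalised at 0.76 J/cm²),
  emulating the fluorescence dip seen in dead-animal controls.  Whether real
  negative deflections are suppressed spiking or a fluoro-thermal artifact
  is deliberately left open: the generator exposes response sign and
  artifact depth as independent knobs and takes no stance.  Default depth is
  0 so recovery tests measure classification, not artifact handling.
* **Spontaneous transients.**  A homogeneous Poisson event process (default
  0.02 events/s, exponentially distributed amplitudes, mean 0.4 ΔF/F0)
  convolved with the same kernel.  No measured spontaneous statistics
  constrain these defaults; they produce occasional visible transients per
  60 s trial.
* **Noise.**  Additive Gaussian noise on ΔF/F0 (default σ = 0.05).  Photon
  shot noise is not modelled — synthesis is at the ROI-trace level.

All randomness flows from a single `numpy.random.SeedSequence` split into
independent child streams for the population draw, the trial order, and each
(neuron, trial) trace, so datasets are bit-identical given (config, seed).

What passing recovery tests show: the analysis chain correctly inverts this
generative model at realistic SNR.  What they do not show: robustness to
motion artifacts, neuropil contamination, segmentation errors, drifting
baselines, or non-Gaussian noise, none of which the generator emulates.

## Trace processing

`ΔF/F0 = (F − F0)/F0` with F0 the mean over the full pre-stimulus baseline
(0–10 s multi-train, 0–3 s long-train; overridable).  A non-positive F0 is a
named error, never a silent division.

Smoothing is a causal scalar Kalman filter (constant-level state-space
model, unit measurement variance, process noise 0.05, initial gain 0.5 —
these are this package's reconstruction of "Kalman smoothing" for display
purposes, not measured values).  All response metrics operate on raw
(unsmoothed) ΔF/F0 by default: smoothing is display-only, and since the
Pearson correlation and per-epoch peak-to-peak statistics are computed on
trial averages, light smoothing changes little; keeping metrics on raw
traces avoids coupling results to filter parameters.

An optional real-data path extracts per-ROI traces from a registered TIFF
stack and an integer label mask (mean pixel value per frame per ROI);
motion correction and segmentation are upstream, external steps.

## Response metrics and classification

* **Reference curve** — mean ΔF/F0 over all neurons of the cohort at the top
  exposure (0.76 J/cm²), restricted to the stimulation window (10–28 s).
  No pre-selection of responders is applied, and the same (positive-going)
  reference is reused for the inhibitory cohort, which is what makes
  negative-going responders come out with negative correlations.
* **Correlation index** — Pearson correlation between a neuron's
  trial-averaged response and the reference over the stimulation window.
  Zero-variance windows yield an *undefined* index (NaN → class "none"),
  never a silent zero.
* **Classification** — strictly greater than +0.2 → positive, strictly less
  than −0.2 → negative, otherwise none.  A value exactly at a threshold is
  none.  The ±0.2 value is taken as given.
* **Amplitude** — each of the six train epochs (onset-to-onset, six equal
  3 s epochs partitioning the 18 s stimulation period) contributes
  `p_i = max − min` of the trial-averaged ΔF/F0; the amplitude is
  `mean(p_1..p_6)` signed by the correlation index, so negative-going
  responders get negative amplitudes.
* **AUC (3–10 s)** — long-train paradigm: maximal contiguous above-zero
  segments of the trial-averaged trace within 3–10 s; segments whose
  maximum is below `min + 0.1·(max − min)` (range over the window) are
  ignored; retained segments are integrated trapezoidally with interpolated
  zero crossings.  Baseline is fixed at 0.
* **Fractions and fits** — per-intensity positive/negative percentages are
  rounded to one decimal, ties away from zero (printing convention).  The
  intensity-dependence fit is ordinary least squares of the cohort mean
  correlation index on radiant exposure, reporting slope, intercept, R² and
  the two-sided slope p-value.
* **Rank tests** — Wilcoxon signed-rank (paired) and Mann–Whitney U
  (unpaired), two-sided; exact null distributions for n ≤ 25 without ties,
  normal approximation with tie correction otherwise.  Identical paired
  samples return p = 1; fully tied unpaired samples are undefined (NaN).

## Monte Carlo light transport

A voxelised weighted-photon random walk on a cubic grid (default 4 mm side,
10 μm pitch, 400³ voxels) through a planar three-layer stack — ACSF, cover
glass, cortex — with per-voxel layer labels (editable for non-planar
geometries).  Photons launch from the tilted fiber face (200 μm core disc,
45° to the horizontal in the x–z plane, tip on the glass top surface) with
polar angle θ such that sin θ is uniform on [0, NA/n] and uniform azimuth.
Transport follows the standard scheme: dimensionless exponential step
lengths consumed through voxels at the local μ_t; partial-weight absorption
μ_a/μ_t deposited per interaction; Henyey–Greenstein deflection with the
local g; unpolarised Fresnel reflection/refraction (normal along the crossed
voxel face) wherever the refractive index changes; Russian roulette below
weight 10⁻⁴ with survival probability 0.1.

**Weight bookkeeping.**  Every weight change is ledgered: launched, absorbed,
escaped, and the net weight created/destroyed by roulette
(`roulette_net = Σ boosts − Σ kills`).  The identity
`launched + roulette_net = absorbed + escaped` holds to float precision on
every run; with roulette disabled (`rr_threshold=0`) the plain
`launched = absorbed + escaped` holds exactly.  Roulette is unbiased, so
`roulette_net` is zero in expectation.

**Optical properties** at 1875 nm are configuration, not results: defaults
are literature-typical placeholders (ACSF/water μ_a = 3 mm⁻¹, μ_s = 0,
n = 1.33; glass μ_a ≈ 0, μ_s = 0, n = 1.52; cortex μ_a = 3 mm⁻¹ —
water-dominated at this wavelength — μ_s = 5 mm⁻¹, g = 0.9, n = 1.36).  The
glass radiant-exposure correction is a single scalar transmission multiplier
applied as the initial photon weight (default 1.0).

The **illuminated region** at an imaging depth (measured from the cortex
surface) is the set of voxels in that plane whose fluence (absorbed/μ_a)
reaches 10% of the plane maximum — the 0.1 fraction is a qualitative choice
mirroring a drawn region, and is a parameter.  A purely geometric fallback
(`cone_mask`) refracts the fiber axis through the layer stack and takes the
disc of radius `core_radius + path · tan(asin(NA/n_cortex))`.  Neurons are
binned illuminated / weakly-illuminated by (x, y) membership at their depth
plane; out-of-grid positions bin as weakly illuminated with a warning.

Validation: pure-absorber depth profiles against Beer–Lambert (binned
z-scores), exact conservation with μ_a = 0, azimuthal symmetry for g = 0,
1/√N scaling of the Monte Carlo standard error, and the lateral displacement
of an oblique collimated beam against ray geometry.

## Population model

The population time course is the convex combination
`0.8 · excitatory mean + 0.2 · inhibitory mean` of cohort grand-mean ΔF/F0
curves — the standard cortical excitatory/inhibitory ratio.  The operation
is intensity-agnostic; the worked example uses 0.42 J/cm².  Output is
bounded by the pointwise component extremes, and swapping weights together
with inputs is an identity (both are tested invariants).

## Numerical choices and degenerate inputs

* Sample windows are half-open; window edges map to indices by rounding
  `time × rate`.
* Correlation values are clipped to [−1, 1] against rounding excursions.
* Photons launched exactly on a grid face are nudged one millionth of a
  voxel along their direction so their starting voxel is unambiguous.
* Degenerate metric inputs (zero-variance windows, all-tied rank-test
  samples, empty trace lists, non-positive F0) raise named errors or return
  explicit NaN — never silent zeros.
* Percentage rounding is half-away-from-zero at one decimal.

## Problem sizes

Test and acceptance runs use deliberately scaled problem sizes chosen to
exercise every code path with tight statistical checks: Monte Carlo runs of
2·10³–10⁵ photons on 100³–200³ grids, synthetic cohorts of 8–200 neurons,
and 20-seed replication for the recovery study (4 000 classified neurons
pooled).  The full-resolution settings (400³ voxels at 10 μm, arbitrary
photon counts, 199-neuron cohorts over 48 trials) are the library defaults
and run unchanged, just longer.

## Known limitations

* Trace-level synthesis: no pixel-level movies, no shot noise, no motion or
  neuropil confounds; segmentation and registration are out of scope.
* The intensity–amplitude law, calcium kernel, spontaneous statistics and
  noise level are plausible defaults, not fitted to recordings.
* Optical properties at 1875 nm are placeholders; absolute fluence values
  and the illuminated-region footprint change with them (the relative,
  geometric behaviour tested here does not).
* No heat-diffusion/temperature model and no time-resolved transport.
* The Kalman filter is a scalar reconstruction for display smoothing, not a
  calibrated denoiser.
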