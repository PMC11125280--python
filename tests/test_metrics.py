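import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inscal.metrics import (
    ClassifierConfig,
    auc_3_10,
    build_reference,
    classification_fractions,
    classify,
    correlation_index,
    count_unique_labeled,
    intensity_fit,
    peak_amplitude,
    rank_compare,
    round_half_away,
    select_top_fraction,
)
from inscal.paradigm import make_paradigm
from inscal.synthetic import calcium_kernel

from conftest import FS, dff_from

WINDOW = (10.0, 28.0)


def template_avg(amplitude=0.3, noise=0.0, seed=0):
    """Deterministic multi-train template response as a DffTrace."""
    paradigm = make_paradigm("multi_train", 0.76)
    n = 1800
    kernel = calcium_kernel(FS)
    impulses = np.zeros(n)
    impulses[(paradigm.train_onsets_s * FS).astype(int)] = 1.0
    values = amplitude * np.convolve(impulses, kernel)[:n]
    if noise:
        values = values + np.random.default_rng(seed).normal(0, noise, n)
    return dff_from(values)


class TestReference:
    def test_single_neuron_reference(self):
        avg = template_avg()
        ref = build_reference([avg], WINDOW)
        np.testing.assert_allclose(ref.values, avg.window_slice(WINDOW))
        assert ref.n_contributing == 1

    def test_identical_cohort(self):
        avg = template_avg()
        ref = build_reference([avg] * 10, WINDOW)
        np.testing.assert_allclose(ref.values, avg.window_slice(WINDOW))

    def test_noisy_cohort_recovers_template(self):
        """With n=100 neurons at per-neuron noise sigma, the cohort mean sits
        within the Monte Carlo error of the generating template: RMS
        deviation under 1.5 SE and 99% of samples within 3 SE."""
        sigma, n = 0.1, 100
        avgs = [template_avg(noise=sigma, seed=s) for s in range(n)]
        ref = build_reference(avgs, WINDOW)
        truth = template_avg().window_slice(WINDOW)
        se = sigma / math.sqrt(n)
        z = (ref.values - truth) / se
        assert math.sqrt(np.mean(z**2)) < 1.5
        assert np.mean(np.abs(z) < 3) > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            build_reference([dff_from(np.zeros(1800))], WINDOW)


class TestCorrelationIndex:
    def test_self_correlation_is_one(self):
        avg = template_avg()
        ref = build_reference([avg], WINDOW)
        assert correlation_index(avg, ref) == pytest.approx(1.0)

    def test_antiphase_is_minus_one(self):
        avg = template_avg()
        ref = build_reference([avg], WINDOW)
        flipped = dff_from(-avg.values)
        assert correlation_index(flipped, ref) == pytest.approx(-1.0)

    def test_offset_invariance(self):
        avg = template_avg()
        ref = build_reference([avg], WINDOW)
        shifted = dff_from(avg.values + 0.7)
        assert correlation_index(shifted, ref) == pytest.approx(1.0)

    def test_zero_variance_is_undefined_not_zero(self):
        ref = build_reference([template_avg()], WINDOW)
        flat = dff_from(np.zeros(1800))
        r = correlation_index(flat, ref)
        assert math.isnan(r)
        assert classify(r) == "none"

    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=-1.0, max_value=1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, gain, offset):
        """Correlation is invariant to positive affine rescaling."""
        avg = template_avg(noise=0.05, seed=4)
        ref = build_reference([template_avg()], WINDOW)
        r0 = correlation_index(avg, ref)
        r1 = correlation_index(dff_from(gain * avg.values + offset), ref)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.35, "positive"),
            (-0.21, "negative"),
            (0.2, "none"),  # strict threshold
            (-0.2, "none"),
            (0.0, "none"),
            (float("nan"), "none"),
        ],
    )
    def test_threshold_rule(self, value, label):
        assert classify(value) == label

    def test_custom_thresholds(self):
        cfg = ClassifierConfig(threshold_pos=0.9, threshold_neg=-0.9)
        assert classify(0.5, cfg) == "none"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(threshold_pos=-0.1, threshold_neg=-0.2)


class TestPeakAmplitude:
    def test_flat_trace(self):
        paradigm = make_paradigm("multi_train", 0.5)
        amp, peaks = peak_amplitude(dff_from(np.zeros(1800)), paradigm, 0.5)
        assert amp == 0.0
        np.testing.assert_array_equal(peaks, 0.0)

    def test_known_excursion_brute_force(self):
        """p_i equals a brute-force max-min scan per 3 s train epoch."""
        paradigm = make_paradigm("multi_train", 0.76)
        avg = template_avg(amplitude=0.4)
        amp, peaks = peak_amplitude(avg, paradigm, correlation_value=0.9)
        for i, onset in enumerate(paradigm.train_onsets_s):
            i0, i1 = int(onset * FS), int((onset + 3.0) * FS)
            seg = avg.values[i0:i1]
            assert peaks[i] == pytest.approx(seg.max() - seg.min())
        assert amp == pytest.approx(peaks.mean())

    def test_negative_correlation_flips_sign(self):
        paradigm = make_paradigm("multi_train", 0.76)
        avg = template_avg(amplitude=0.4)
        pos, peaks = peak_amplitude(avg, paradigm, 0.9)
        neg, _ = peak_amplitude(avg, paradigm, -0.9)
        assert neg == pytest.approx(-pos)

    def test_requires_six_trains(self):
        with pytest.raises(ValueError):
            peak_amplitude(dff_from(np.zeros(900)), make_paradigm("long_train", 0.4), 0.5)


class TestAuc310:
    def test_all_zero(self):
        assert auc_3_10(dff_from(np.zeros(900))) == 0.0

    def test_triangle_area(self):
        """A height-1 triangle with a 2 s base inside 3-10 s has area 1."""
        t = np.arange(900) / FS
        y = np.clip(1.0 - np.abs(t - 6.0), 0.0, None)
        assert auc_3_10(dff_from(y)) == pytest.approx(1.0, abs=1e-3)

    def test_small_peak_discarded(self):
        """A 0.05-high peak is below 10% of a 1.0 range and is ignored;
        expected area brute-forced from the big peak alone."""
        t = np.arange(900) / FS
        big = np.clip(1.0 - np.abs(t - 5.0) / 0.5, 0.0, None)
        small = np.clip(0.05 * (1.0 - np.abs(t - 8.0) / 0.5), 0.0, None)
        y = big + small
        area = auc_3_10(dff_from(y))
        expected = np.trapezoid(big[(t >= 3) & (t <= 10)], t[(t >= 3) & (t <= 10)])
        assert area == pytest.approx(expected, rel=1e-2)
        # sanity of the threshold arithmetic: 0.05 < 0.1 x (1.0 - 0)
        assert 0.05 < 0.1 * (y.max() - min(y.min(), 0))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            auc_3_10(dff_from(np.zeros(100)))


class TestClassificationFractions:
    def make_profiles(self, counts, total, intensities):
        import pandas as pd

        rows = []
        for q, n_pos in zip(intensities, counts):
            labels = ["positive"] * n_pos + ["none"] * (total - n_pos)
            rows += [{"intensity": q, "label": l} for l in labels]
        return pd.DataFrame(rows)

    def test_cohort_percentages(self):
        """Counts out of 199 neurons map to the printed one-decimal
        percentages."""
        counts = [5, 24, 73, 76, 58, 64, 104]
        intensities = [0.16, 0.29, 0.42, 0.50, 0.59, 0.68, 0.76]
        out = classification_fractions(self.make_profiles(counts, 199, intensities))
        assert list(out["pct_pos"]) == [2.5, 12.1, 36.7, 38.2, 29.1, 32.2, 52.3]

    def test_zero_positive(self):
        out = classification_fractions(self.make_profiles([0], 50, [0.16]))
        assert out.loc[0, "pct_pos"] == 0.0

    def test_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        labels = rng.choice(["positive", "negative", "none"], size=500)
        df = pd.DataFrame({"intensity": rng.choice([0.1, 0.2], 500), "label": labels})
        out = classification_fractions(df)
        total = out["pct_pos"] + out["pct_neg"] + out["pct_none"]
        assert np.all(np.abs(total - 100.0) <= 0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_fractions([])


def test_round_half_away():
    assert round_half_away(12.05) == 12.1
    assert round_half_away(-12.05) == -12.1
    assert round_half_away(2.44) == 2.4


class TestIntensityFit:
    def test_collinear(self):
        fit = intensity_fit([(x, 2 * x + 1) for x in (0.1, 0.3, 0.5, 0.7)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant(self):
        fit = intensity_fit([(x, 0.4) for x in (0.1, 0.3, 0.5)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(12)
        xs = [0.16, 0.29, 0.42, 0.50, 0.59, 0.68, 0.76]
        pts = [(x, 0.3 * x + rng.normal(0, 0.02)) for x in xs]
        fit = intensity_fit(pts)
        assert abs(fit.slope - 0.3) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            intensity_fit([(0.1, 0.1), (0.2, 0.2)])


class TestRankCompare:
    def test_identical_paired(self):
        assert rank_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True) == 1.0

    def test_complete_separation_exact(self):
        """n=m=10 with no overlap: p equals the exact minimal two-sided tail
        2/C(20,10) of the U distribution."""
        a = np.arange(10, dtype=float)
        b = np.arange(100, 110, dtype=float)
        p = rank_compare(a, b, paired=False)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(30)
        other = rng.standard_normal(30)
        ps = [rank_compare(base, other + shift, paired=False) for shift in (0.3, 1.0, 2.5)]
        assert ps[0] > ps[1] > ps[2]

    def test_all_tied_unpaired_undefined(self):
        assert math.isnan(rank_compare([1.0, 1.0], [1.0, 1.0, 1.0], paired=False))

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            rank_compare([1.0], [1.0, 2.0], paired=True)


def test_count_unique_labeled():
    assert count_unique_labeled(219, 189, 25) == 383
    with pytest.raises(ValueError):
        count_unique_labeled(10, 10, 11)


def test_select_top_fraction():
    rng = np.random.default_rng(0)
    values = rng.standard_normal(335)
    idx = select_top_fraction(values, 0.10)
    assert idx.size == 34  # ceil(0.1 x 335)
    assert values[idx].min() >= np.sort(values)[-34]
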