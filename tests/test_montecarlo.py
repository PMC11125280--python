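import math
import warnings

import numpy as np
import pytest

from inscal.montecarlo import (
    FiberSpec,
    Layer,
    OpticalProperties,
    bin_neurons,
    build_tissue,
    cone_mask,
    default_layers,
    illuminated_region,
    launch_photons,
    run_monte_carlo,
)


def homogeneous(mu_a, mu_s, g=0.0, n=1.33, extent=2.0, pitch=0.02):
    layer = Layer("medium", extent, OpticalProperties(mu_a, mu_s, g, n))
    return build_tissue([layer], extent_mm=extent, voxel_pitch_mm=pitch)


def vertical_fiber(na=0.01, tip=(1.0, 1.0, 0.0)):
    return FiberSpec(tilt_deg=90.0, tip_position_mm=tip, numerical_aperture=na)


class TestBuildTissue:
    def test_default_grid_is_400_cubed(self):
        tissue = build_tissue()
        assert tissue.voxels_per_axis == 400
        assert len(tissue.layers) == 3

    def test_pitch_20um(self):
        tissue = build_tissue(default_layers(), extent_mm=4.0, voxel_pitch_mm=0.02)
        assert tissue.voxels_per_axis == 200

    def test_single_layer_homogeneous(self):
        tissue = homogeneous(1.0, 0.0)
        assert np.all(tissue.label_grid == 0)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            build_tissue(default_layers(), extent_mm=4.0, voxel_pitch_mm=0.0301)

    def test_layer_ordering(self):
        tissue = build_tissue()  # ACSF 0.5 mm / glass 0.17 mm / cortex
        assert tissue.label_grid[0, 0, 0] == 0
        assert tissue.label_grid[0, 0, 55] == 1  # 0.55 mm deep: glass
        assert tissue.label_grid[0, 0, 399] == 2

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=-1.0, mu_s=0.0)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=0.0, mu_s=0.0, g=1.5)


class TestLaunch:
    def test_collimated_limit(self):
        fiber = FiberSpec(tilt_deg=90.0, numerical_aperture=1e-6)
        _, dirs, _ = launch_photons(fiber, 500, np.random.default_rng(0))
        np.testing.assert_allclose(dirs - fiber.axis, 0.0, atol=1e-6)

    def test_divergence_bounded_by_na(self):
        """Over 10^4 launches the polar angle never exceeds asin(NA/n)."""
        fiber = FiberSpec(tilt_deg=45.0, numerical_aperture=0.37)
        _, dirs, _ = launch_photons(fiber, 10_000, np.random.default_rng(1), n_medium=1.33)
        cos_t = dirs @ fiber.axis
        max_angle = np.arccos(np.clip(cos_t, -1, 1)).max()
        assert max_angle <= math.asin(0.37 / 1.33) + 1e-9

    def test_mean_position_is_tip_centre(self):
        fiber = FiberSpec(tip_position_mm=(1.5, 2.0, 0.5))
        pos, _, _ = launch_photons(fiber, 20_000, np.random.default_rng(2))
        # disc radius 0.1 mm; MC error of the mean ~ 0.1/2/sqrt(N)
        np.testing.assert_allclose(pos.mean(axis=0), (1.5, 2.0, 0.5), atol=0.002)

    def test_weight_is_glass_transmission(self):
        fiber = FiberSpec(glass_transmission=0.8)
        _, _, w = launch_photons(fiber, 10, np.random.default_rng(0))
        np.testing.assert_allclose(w, 0.8)


class TestTransport:
    def test_no_absorption_everything_escapes(self):
        tissue = homogeneous(0.0, 2.0, g=0.5)
        fmap = run_monte_carlo(tissue, vertical_fiber(), 5_000, seed=2)
        assert fmap.totals["absorbed"] == 0.0
        assert fmap.totals["escaped"] == pytest.approx(fmap.totals["launched"])

    def test_weight_conservation_with_scattering_and_roulette(self):
        tissue = homogeneous(0.5, 5.0, g=0.9, n=1.37)
        fmap = run_monte_carlo(tissue, vertical_fiber(), 20_000, seed=3)
        assert fmap.conservation_error() < 1e-6
        assert fmap.absorbed.min() >= 0.0

    def test_beer_lambert_depth_profile(self):
        """Pure absorber: binned on-axis deposition matches the closed-form
        exponential attenuation within Monte Carlo error."""
        n_photons = 30_000
        tissue = homogeneous(1.0, 0.0)
        fmap = run_monte_carlo(tissue, vertical_fiber(), n_photons, seed=1)
        prof = fmap.absorbed.sum(axis=(0, 1)) / fmap.totals["launched"]
        edges = np.arange(101) * 0.02
        expected = np.exp(-edges[:-1]) - np.exp(-edges[1:])
        se = np.sqrt(expected * (1 - expected) / n_photons)
        z = (prof - expected) / se
        assert np.abs(z).max() < 4.0
        assert np.mean(np.abs(z) < 3.0) > 0.98

    def test_forward_beam_does_not_deposit_behind_launch(self):
        tissue = homogeneous(1.0, 0.0, extent=2.0, pitch=0.02)
        fmap = run_monte_carlo(tissue, vertical_fiber(tip=(1.0, 1.0, 1.0)), 5_000, seed=4)
        assert fmap.absorbed[:, :, :49].sum() == 0.0  # nothing above the tip

    def test_azimuthal_symmetry_isotropic_scattering(self):
        """g=0 homogeneous medium, vertical beam: quadrant deposition sums
        agree within sampling error."""
        tissue = homogeneous(1.0, 3.0, g=0.0)
        fmap = run_monte_carlo(tissue, vertical_fiber(), 40_000, seed=5)
        a = fmap.absorbed
        q = np.array(
            [
                a[:50, :50].sum(),
                a[:50, 50:].sum(),
                a[50:, :50].sum(),
                a[50:, 50:].sum(),
            ]
        )
        assert q.std() / q.mean() < 0.05

    def test_deterministic_per_seed(self):
        tissue = homogeneous(1.0, 2.0, g=0.5, extent=1.0, pitch=0.05)
        fiber = vertical_fiber(tip=(0.5, 0.5, 0.0))
        a = run_monte_carlo(tissue, fiber, 2_000, seed=9)
        b = run_monte_carlo(tissue, fiber, 2_000, seed=9)
        np.testing.assert_array_equal(a.absorbed, b.absorbed)
        assert a.totals == b.totals

    def test_standard_error_halves_with_4x_photons(self):
        """The MC standard error of the absorbed fraction scales as
        1/sqrt(N): 4x photons gives ~half the spread over replicate seeds."""
        tissue = homogeneous(1.0, 3.0, g=0.7, extent=1.0, pitch=0.05)
        fiber = vertical_fiber(tip=(0.5, 0.5, 0.0))

        def spread(n):
            fr = [
                run_monte_carlo(tissue, fiber, n, seed=s).totals["absorbed"] / n
                for s in range(12)
            ]
            return np.std(fr)

        ratio = spread(800) / spread(3200)
        assert 1.2 < ratio < 3.3


class TestIlluminatedRegion:
    def test_uniform_plane_full_mask(self):
        tissue = homogeneous(1.0, 0.0)
        fmap = run_monte_carlo(tissue, vertical_fiber(), 100, seed=0)
        fmap.absorbed[:] = 1.0  # uniform deposition by construction
        mask = illuminated_region(fmap, depth_um=100)
        assert mask.all()

    def test_threshold_one_keeps_only_argmax(self):
        tissue = homogeneous(1.0, 0.0)
        fmap = run_monte_carlo(tissue, vertical_fiber(), 100, seed=0)
        fmap.absorbed[:] = 0.0
        fmap.absorbed[10, 20, 5] = 5.0
        mask = illuminated_region(fmap, depth_um=100, threshold_fraction=1.0)
        assert mask.sum() == 1 and mask[10, 20]

    def test_oblique_beam_centroid_displacement(self):
        """A collimated 45-degree beam in a uniform-index absorber lands
        displaced laterally from the tip projection by depth x tan(45 deg)
        (fiber face fully inside the medium)."""
        tissue = homogeneous(1.0, 0.0, n=1.36)
        tip = (0.5, 1.0, 0.2)
        fiber = FiberSpec(tilt_deg=45.0, tip_position_mm=tip, numerical_aperture=1e-4)
        fmap = run_monte_carlo(tissue, fiber, 30_000, seed=6)
        mask = illuminated_region(fmap, depth_um=500.0)
        centroid_mm = np.argwhere(mask).mean(axis=0) * tissue.voxel_pitch_mm
        iz = int(0.5 / tissue.voxel_pitch_mm)
        z_plane = (iz + 0.5) * tissue.voxel_pitch_mm
        expected_x = tip[0] + (z_plane - tip[2]) * math.tan(math.radians(45.0))
        assert abs(centroid_mm[0] - expected_x) < 0.05
        assert abs(centroid_mm[1] - 1.0) < 0.05

    def test_depth_outside_grid_rejected(self):
        tissue = homogeneous(1.0, 0.0)
        fmap = run_monte_carlo(tissue, vertical_fiber(), 100, seed=0)
        with pytest.raises(ValueError):
            illuminated_region(fmap, depth_um=5_000)

    def test_cone_mask_matches_geometry(self):
        tissue = homogeneous(2.0, 0.0, n=1.36)
        fiber = FiberSpec(tilt_deg=45.0, tip_position_mm=(0.5, 1.0, 0.0))
        mask = cone_mask(tissue, fiber, depth_um=300.0)
        centroid_mm = np.argwhere(mask).mean(axis=0) * tissue.voxel_pitch_mm
        assert abs(centroid_mm[0] - 0.8) < 0.03
        assert abs(centroid_mm[1] - 1.0) < 0.03


class TestBinNeurons:
    def test_membership(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:7, 4:7] = True
        pitch = 10.0
        labels = bin_neurons(np.array([[50.0, 50.0], [5.0, 5.0]]), mask, pitch)
        assert labels == ["illuminated", "weakly_illuminated"]

    def test_all_covering_mask(self):
        mask = np.ones((5, 5), dtype=bool)
        labels = bin_neurons(np.array([[1.0, 1.0], [40.0, 40.0]]), mask, 10.0)
        assert labels == ["illuminated"] * 2

    def test_out_of_grid_warns(self):
        mask = np.ones((5, 5), dtype=bool)
        with pytest.warns(UserWarning):
            labels = bin_neurons(np.array([[999.0, 10.0]]), mask, 10.0)
        assert labels == ["weakly_illuminated"]
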