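"""Copy-number estimation, geometry and nuclei staging."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineagefish as lf
from lineagefish.quant import StagePoint

from conftest import make_calibration_stack, make_single_cell_stack


class TestSphereVolume:
    def test_printed_cell_volumes(self):
        """6.0 µm and 3.5 µm cells have volumes 113 and 22 µm³."""
        assert round(lf.sphere_volume(6.0)) == 113
        assert round(lf.sphere_volume(3.5)) == 22

    def test_zero_and_negative(self):
        assert lf.sphere_volume(0.0) == 0.0
        with pytest.raises(ValueError):
            lf.sphere_volume(-1.0)

    @given(st.floats(min_value=0.01, max_value=50.0),
           st.floats(min_value=0.01, max_value=50.0))
    def test_strictly_increasing_and_closed_form(self, d1, d2):
        v1, v2 = lf.sphere_volume(d1), lf.sphere_volume(d2)
        assert v1 == pytest.approx(math.pi / 6 * d1**3)
        if d1 < d2:
            assert v1 < v2


class TestCopyNumberArithmetic:
    @pytest.mark.parametrize(
        "si_total,si_bkgd,si_spot,expected",
        [(1000.0, 100.0, 90.0, 10.0), (100.0, 100.0, 50.0, 0.0)],
    )
    def test_formula(self, si_total, si_bkgd, si_spot, expected):
        assert lf.copy_number(si_total, si_bkgd, si_spot) == expected

    def test_negative_clipped_to_zero(self):
        assert lf.copy_number(50.0, 100.0, 10.0) == 0.0

    def test_nonpositive_si_spot_rejected(self):
        with pytest.raises(ValueError):
            lf.copy_number(100.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "copies,volume,expected",
        [
            (11.6, lf.sphere_volume(6.0), 0.1),  # printed mother concentration
            (0.0, 5.0, 0.0),
        ],
    )
    def test_concentration(self, copies, volume, expected):
        assert round(lf.concentration(copies, volume), 1) == expected

    def test_concentration_in_printed_band(self):
        """14.1 copies in a 6.0 µm cell lies in the 0.1–0.2 copies/µm³ band."""
        c = lf.concentration(14.1, lf.sphere_volume(6.0))
        assert 0.1 <= c <= 0.2

    def test_concentration_needs_positive_volume(self):
        with pytest.raises(ValueError):
            lf.concentration(1.0, 0.0)


class TestRoiIntegration:
    def test_constant_field_equals_area_times_slices(self):
        grid = lf.VoxelGrid(shape=(10, 80, 80))
        stack = lf.ImageStack({"x": np.ones(grid.shape)}, grid)
        roi = lf.SphericalROI((4.8, 4.8, 2.5), 3.0)
        slab = grid.z_slab(2.5 - 1.5, 2.5 + 1.5)
        area = grid.disk_mask(4.8, 4.8, 1.5).sum()
        assert lf.integrate_roi_signal(stack, roi, "x") == pytest.approx(
            float(area * len(slab)))

    def test_all_zero_image(self):
        grid = lf.VoxelGrid(shape=(8, 40, 40))
        stack = lf.ImageStack({"x": np.zeros(grid.shape)}, grid)
        assert lf.integrate_roi_signal(
            stack, lf.SphericalROI((2.4, 2.4, 2.0), 2.0), "x") == 0.0

    def test_planted_spots_recovered_within_two_percent(self):
        stack, truth, roi = make_single_cell_stack(
            10, noise=lf.NoiseModel.none(), seed=3)
        si = lf.integrate_roi_signal(stack, roi, "egl-1")
        mean_planted = truth.mean_spot_intensity("cell", "egl-1")
        assert si == pytest.approx(10 * mean_planted, rel=0.02)

    def test_out_of_bounds_roi_names_the_bound(self):
        grid = lf.VoxelGrid(shape=(8, 40, 40))
        stack = lf.ImageStack({"x": np.zeros(grid.shape)}, grid)
        with pytest.raises(ValueError, match="upper x"):
            lf.integrate_roi_signal(
                stack, lf.SphericalROI((4.7, 2.4, 2.0), 1.0), "x")


class TestBackground:
    def test_uniform_background_value(self):
        grid = lf.VoxelGrid(shape=(16, 160, 160))
        stack = lf.ImageStack({"x": np.full(grid.shape, 2.0)}, grid)
        roi = lf.SphericalROI((9.6, 9.6, 4.0), 3.0)
        slab = grid.z_slab(4.0 - 1.5, 4.0 + 1.5)
        area = grid.disk_mask(9.6, 9.6, 1.5).sum()
        est = lf.estimate_background(stack, roi, channel="x")
        assert est == pytest.approx(2.0 * area * len(slab), rel=1e-6)

    def test_gradient_bias_below_five_percent_of_spot(self):
        """Empty-ROI residual under a linear tilt stays ≪ one spot intensity."""
        noise = lf.NoiseModel(background_level=5.0, background_gradient=0.05,
                              shot_noise=False, read_noise_sd=0.0)
        stack, _, roi = make_single_cell_stack(0, noise=noise, seed=1)
        resid = (lf.integrate_roi_signal(stack, roi, "egl-1")
                 - lf.estimate_background(stack, roi, channel="egl-1"))
        assert abs(resid) < 0.05 * 500.0


class TestSpotCalibration:
    def test_uniform_spots_zero_noise_within_five_percent(self):
        stack, _ = make_calibration_stack(
            intensity_cv=0.0, noise=lf.NoiseModel.none(), seed=1)
        si = lf.calibrate_spot_intensity(stack, channel="egl-1")
        assert si == pytest.approx(500.0, rel=0.05)

    def test_noisy_variable_spots_within_ten_percent(self):
        stack, _ = make_calibration_stack(intensity_cv=0.2, seed=2)
        si = lf.calibrate_spot_intensity(stack, channel="egl-1")
        assert si == pytest.approx(500.0, rel=0.10)

    def test_zero_spots_raises(self):
        grid = lf.VoxelGrid(shape=(12, 60, 60))
        stack = lf.ImageStack({"x": np.zeros(grid.shape)}, grid)
        with pytest.raises(ValueError, match="manual"):
            lf.calibrate_spot_intensity(stack, channel="x")

    def test_scale_invariance_of_copy_number(self):
        """Scaling the image by c scales all signals by c; copies unchanged."""
        stack, _, roi = make_single_cell_stack(8, seed=13)
        cal, _ = make_calibration_stack(seed=14)
        c = 3.7
        scaled = stack.scaled(c)
        st1 = lf.integrate_roi_signal(stack, roi, "egl-1")
        st2 = lf.integrate_roi_signal(scaled, roi, "egl-1")
        sb1 = lf.estimate_background(stack, roi, channel="egl-1")
        sb2 = lf.estimate_background(scaled, roi, channel="egl-1")
        sp1 = lf.calibrate_spot_intensity(cal, channel="egl-1")
        sp2 = lf.calibrate_spot_intensity(cal.scaled(c), channel="egl-1")
        # stacks are float32; scaling commutes with summation to ~1e-7
        assert st2 == pytest.approx(c * st1, rel=1e-6)
        assert sb2 == pytest.approx(c * sb1, rel=1e-6)
        assert sp2 == pytest.approx(c * sp1, rel=1e-6)
        assert lf.copy_number(st2, sb2, sp2) == pytest.approx(
            lf.copy_number(st1, sb1, sp1), rel=1e-6)


class TestFullEstimator:
    def test_single_cell_count_twelve_within_two(self, calibrated_si_spot):
        stack, _, roi = make_single_cell_stack(12, seed=1)
        si_total = lf.integrate_roi_signal(stack, roi, "egl-1")
        si_bkgd = lf.estimate_background(stack, roi, channel="egl-1")
        est = lf.copy_number(si_total, si_bkgd, calibrated_si_spot)
        assert abs(est - 12) <= 2.0

    def test_recovery_over_100_cells(self, calibrated_si_spot):
        """MAE ≤ max(1, 10% of truth) and |bias| ≤ 0.5 over counts 0–30."""
        rng = np.random.default_rng(42)
        errors, trues = [], []
        for i in range(100):
            true = int(rng.integers(0, 31))
            stack, _, roi = make_single_cell_stack(true, seed=1000 + i)
            si_total = lf.integrate_roi_signal(stack, roi, "egl-1")
            si_bkgd = lf.estimate_background(stack, roi, channel="egl-1")
            errors.append(lf.copy_number(si_total, si_bkgd,
                                         calibrated_si_spot) - true)
            trues.append(true)
        errors = np.asarray(errors)
        mae = np.abs(errors).mean()
        assert mae <= max(1.0, 0.1 * np.mean(trues))
        assert abs(errors.mean()) <= 0.5

    def test_zero_noise_concentration_pipeline(self):
        """concentration(copy_number(...), volume) matches truth within 2%."""
        stack, truth, roi = make_single_cell_stack(
            15, noise=lf.NoiseModel.none(), seed=7)
        si_total = lf.integrate_roi_signal(stack, roi, "egl-1")
        si_bkgd = lf.estimate_background(stack, roi, channel="egl-1")
        si_spot = truth.mean_spot_intensity("cell", "egl-1")
        vol = lf.sphere_volume(roi.diameter)
        conc = lf.concentration(
            lf.copy_number(si_total, si_bkgd, si_spot), vol)
        assert conc == pytest.approx(15 / vol, rel=0.02)


class TestNucleiCount:
    def test_empty_stack_is_zero(self):
        grid = lf.VoxelGrid(shape=(8, 40, 40))
        assert lf.count_nuclei(
            lf.ImageStack({"dapi": np.zeros(grid.shape)}, grid)) == 0

    @pytest.mark.parametrize("n,shape", [
        (10, (28, 170, 170)),
        (180, (28, 170, 170)),
        (400, (36, 220, 220)),
    ])
    def test_well_separated_counts_within_one_percent(self, n, shape):
        grid = lf.VoxelGrid(dx=0.2, dy=0.2, dz=0.5, shape=shape)
        stack, _ = lf.simulate_embryo_image(
            [], nuclei_count=n, voxel_grid=grid, seed=5 + n)
        assert abs(lf.count_nuclei(stack) - n) <= max(1, round(0.01 * n))

    def test_half_contrast_fifty_within_two(self):
        grid = lf.VoxelGrid(dx=0.2, dy=0.2, dz=0.5, shape=(28, 170, 170))
        stack, _ = lf.simulate_embryo_image(
            [], nuclei_count=50, voxel_grid=grid, seed=7,
            nuclei_intensity=10000.0)
        assert abs(lf.count_nuclei(stack) - 50) <= 2


class TestFallbackAverage:
    @pytest.mark.parametrize("vals,expected", [
        ((2.0, 3.0, 4.0, 3.0), 3.0),
        ((0.0, 0.0, 0.0, 0.0), 0.0),
    ])
    def test_mean_of_four(self, vals, expected):
        assert lf.fallback_positional_average(vals) == expected

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            lf.fallback_positional_average([1.0, 2.0, 3.0])

    def test_recovers_local_mean_from_estimates(self, calibrated_si_spot):
        """Four positional estimates average near the local true mean."""
        ests = []
        for i, true in enumerate([5, 6, 5, 4]):
            stack, _, roi = make_single_cell_stack(true, seed=300 + i)
            si_total = lf.integrate_roi_signal(stack, roi, "egl-1")
            si_bkgd = lf.estimate_background(stack, roi, channel="egl-1")
            ests.append(lf.CopyNumberEstimate.from_signals(
                f"cell{i}", "egl-1", si_total, si_bkgd, calibrated_si_spot))
        avg = lf.fallback_positional_average(ests)
        assert avg == pytest.approx(5.0, abs=1.0)


class TestStagePoint:
    def test_concentration_lookup(self):
        est = lf.CopyNumberEstimate.from_signals(
            "MSpaap", "egl-1", 1000.0, 100.0, 90.0)
        sp = StagePoint("e1", 175, [est], {"MSpaap": 6.0})
        assert sp.concentration_of("MSpaap", "egl-1") == pytest.approx(
            10.0 / lf.sphere_volume(6.0))
        with pytest.raises(KeyError):
            sp.concentration_of("MSpaap", "ced-3")
        with pytest.raises(ValueError):
            StagePoint("e1", -1, [], {})
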