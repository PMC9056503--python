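"""Spot-shape fitting, fluence maps and surface dose."""

import numpy as np
import pytest

from actipet.beam import (
    SpotPlan,
    SpotShapeModel,
    dose_map,
    fit_gaussian_spot,
    fit_sigma_polynomial,
    fluence_at,
    fluence_map,
    mean_stopping_power,
    reference_plan,
    sigma_at,
    surface_dose,
)
from actipet.synthetic import simulate_spot_image


class TestSpotShape:
    def test_constant_model_independent_of_z(self):
        m = SpotShapeModel.constant(0.78, 0.89)
        assert sigma_at(m, 0.0) == sigma_at(m, 7.5) == (0.78, 0.89)

    def test_calibrated_model_reproduces_study_spreads(self):
        # quadratics built to pass through σx = 0.78, σy = 0.89 mm at the
        # tumour distance z = 7.5 cm
        m = SpotShapeModel((0.405, 0.02, 0.004), (0.515, 0.02, 0.004))
        sx, sy = sigma_at(m, 7.5)
        assert sx == pytest.approx(0.78, abs=1e-12)
        assert sy == pytest.approx(0.89, abs=1e-12)

    def test_out_of_domain_and_nonpositive_sigma_rejected(self):
        m = SpotShapeModel((0.1, -0.1, 0.0), (0.5, 0.0, 0.0), (0.0, 5.0))
        with pytest.raises(ValueError, match="domain"):
            sigma_at(m, 11.0)
        with pytest.raises(ValueError, match="non-positive"):
            sigma_at(m, 2.0)

    def test_polynomial_fit_exact_on_noiseless_points(self):
        truth = (0.4, 0.03, 0.004)
        z = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        s = truth[0] + truth[1] * z + truth[2] * z**2
        model = fit_sigma_polynomial(list(zip(z, s)))
        assert np.allclose(model.coeffs_x, truth, atol=1e-9)
        assert np.allclose(model.coeffs_y, truth, atol=1e-9)

    def test_polynomial_fit_recovers_truth_from_noisy_points(self, rng):
        truth = (0.4, 0.03, 0.004)
        z = np.linspace(0, 10, 40)
        noise_sd = 0.005
        s = truth[0] + truth[1] * z + truth[2] * z**2 \
            + rng.normal(0, noise_sd, z.size)
        model = fit_sigma_polynomial(list(zip(z, s)))
        # standard errors from the design matrix
        X = np.vander(z, 3, increasing=True)
        se = noise_sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        for c, t, s_e in zip(model.coeffs_x, truth, se):
            assert abs(c - t) < 3 * s_e

    def test_constant_observations_give_zero_slope_and_curvature(self):
        obs = [(z, 0.5) for z in [0.0, 3.0, 6.0, 9.0]]
        model = fit_sigma_polynomial(obs)
        assert model.coeffs_x[1] == pytest.approx(0.0, abs=1e-12)
        assert model.coeffs_x[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_sigma_polynomial([(0.0, 0.5), (1.0, 0.6), (1.0, 0.6)])


class TestGaussianSpotFit:
    def test_noiseless_recovery_within_1_percent(self):
        img = simulate_spot_image(0.78, 0.89, pitch_mm=0.05)
        sx, sy, centre = fit_gaussian_spot(img, 0.05)
        assert sx == pytest.approx(0.78, rel=0.01)
        assert sy == pytest.approx(0.89, rel=0.01)
        assert centre[0] == pytest.approx(4.0, abs=0.01)

    def test_isotropic_spot_gives_equal_spreads(self):
        img = simulate_spot_image(0.6, 0.6, pitch_mm=0.05)
        sx, sy, _ = fit_gaussian_spot(img, 0.05)
        assert sx == pytest.approx(sy, rel=1e-6)

    def test_noisy_recovery_within_5_percent(self):
        img = simulate_spot_image(0.78, 0.89, pitch_mm=0.05, snr=20, seed=3)
        sx, sy, _ = fit_gaussian_spot(img, 0.05)
        assert sx == pytest.approx(0.78, rel=0.05)
        assert sy == pytest.approx(0.89, rel=0.05)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            fit_gaussian_spot(np.ones((20, 20)), 0.05)
        with pytest.raises(ValueError):
            fit_gaussian_spot(np.zeros((20, 20)), 0.05)


class TestFluence:
    def test_single_centred_spot_closed_form(self):
        plan = SpotPlan.grid(1, 1.2, 10.0, 6.0, 7.5)
        n = plan.total_protons
        expected = n / (2 * np.pi * 0.78 * 0.89) * 100  # 1/mm² -> 1/cm²
        assert fluence_at(plan, 0.78, 0.89, 0.0, 0.0) == pytest.approx(expected)

    def test_protons_per_spot_from_charge(self):
        plan = reference_plan()
        assert plan.spots[0].protons == pytest.approx(
            6.0e-9 * 10.0 / 1.602176634e-19)
        assert len(plan.spots) == 9

    def test_study_plan_central_fluence(self):
        fmap = fluence_map(reference_plan(), 0.78, 0.89)
        assert fmap.value_at_centre() == pytest.approx(2.5e13, rel=0.05)

    def test_grid_integral_conserves_protons(self):
        plan = reference_plan()
        fmap = fluence_map(plan, 0.78, 0.89)
        assert fmap.integral_protons() == pytest.approx(
            plan.total_protons, rel=1e-3)

    def test_small_grid_triggers_edge_warning_or_error(self):
        plan = reference_plan()
        with pytest.warns(UserWarning, match="edge"):
            fluence_map(plan, 0.78, 0.89, half_extent_mm=2.0)
        with pytest.raises(ValueError, match="edge"):
            fluence_map(plan, 0.78, 0.89, half_extent_mm=2.0,
                        edge_action="error")


class TestSurfaceDose:
    def test_zero_fluence_zero_dose(self, water):
        assert surface_dose(0.0, 7.5, 100, water) == 0.0

    def test_study_surface_dose(self, water):
        assert surface_dose(2.5e13, 7.5, 100, water) == pytest.approx(
            2.4e5, rel=0.05)

    def test_linearity_in_fluence(self, water):
        d1 = surface_dose(1e13, 7.5, 100, water)
        d2 = surface_dose(2e13, 7.5, 100, water)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_slab_thicker_than_range_rejected(self, water):
        with pytest.raises(ValueError):
            surface_dose(1e13, 2.0, 5000, water)

    def test_mean_stopping_power_exceeds_entry_value(self, water):
        # the proton slows inside the slab, so the slab mean is above S(E0)
        from actipet.stopping import interpolate_sp

        assert mean_stopping_power(water, 7.5, 100) > interpolate_sp(water, 7.5)


class TestDoseMap:
    def test_central_dose_matches_surface_dose_of_central_fluence(self, water):
        plan = reference_plan()
        fmap = fluence_map(plan, 0.78, 0.89)
        dmap = dose_map(plan, 0.78, 0.89, water, 100)
        expected = surface_dose(fmap.value_at_centre(), 7.5, 100, water)
        assert dmap.value_at_centre() == pytest.approx(expected, rel=1e-9)

    def test_dose_proportional_to_fluence_everywhere(self, water):
        plan = reference_plan()
        fmap = fluence_map(plan, 0.78, 0.89)
        dmap = dose_map(plan, 0.78, 0.89, water, 100)
        ratio = dmap.values[fmap.values > 0] / fmap.values[fmap.values > 0]
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_max_dose_at_grid_centre_for_symmetric_plan(self, water):
        dmap = dose_map(reference_plan(), 0.78, 0.89, water, 100)
        iy, ix = np.unravel_index(np.argmax(dmap.values), dmap.values.shape)
        assert abs(dmap.x_mm[ix]) < 1e-9
        assert abs(dmap.y_mm[iy]) < 1e-9

    def test_isodose_contours_enclose_high_dose_region(self, water):
        dmap = dose_map(reference_plan(), 0.78, 0.89, water, 100)
        level = 0.5 * dmap.values.max()
        contours = dmap.isodose_contours([level])[level]
        assert contours, "expected at least one contour polygon"
        xy = np.asarray(contours[0])
        assert np.max(np.abs(xy)) < 5.0  # stays inside the map
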