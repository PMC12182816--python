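"""Concomitant basis, surface fitting, guard and correction operators."""

import numpy as np
import pytest

from pccor.background import (
    ConcomitantModel,
    apply_correction,
    canonical_coefficients,
    concomitant_shape,
    design_matrix,
    fit_surface,
    linear_correction,
    overfit_guard,
    phantom_correction,
    solve_least_squares,
)
from pccor.core import AlgoParams, ConfigurationError, fov_center_roi, \
    plane_coordinates
from pccor.simulate import PhantomConfig, generate, oblique_geometry
from pccor.static_tissue import StaticMasks, build_static_masks


def _coords(rows=32, cols=32, tilt=15.0, roll=5.0, offset=(2, -1, 6)):
    geom = oblique_geometry(rows, cols, (4.0, 4.0), tilt, roll, offset)
    return geom, plane_coordinates(geom)


class TestConcomitantShape:
    def test_raw_shape_vanishes_at_isocenter(self):
        # a plane through the isocenter: the pixel nearest (0,0,0) has the
        # smallest |raw shape| and it tends to zero with the distance
        geom, coords = _coords(offset=(0, 0, 0), tilt=0.0, roll=0.0)
        x, y, z = coords
        model = ConcomitantModel()
        a, b, c, d = model.moments
        raw = a * (x**2 + y**2) / 4 + b * z**2 - c * x * z - d * y * z
        center = np.unravel_index(np.argmin(x**2 + y**2 + z**2), x.shape)
        assert abs(raw[center]) < 0.1  # sub-pixel distance from isocenter

    def test_in_plane_axial_reduces_to_radial_bowl(self):
        geom, coords = _coords(tilt=0.0, roll=0.0, offset=(0, 0, 0))
        x, y, z = coords
        assert np.all(z == 0)
        shape = concomitant_shape(coords, ConcomitantModel(moments=(1, 1, 0, 0)))
        bowl = (x**2 + y**2) / 4
        ratio = shape[bowl > 0] / bowl[bowl > 0]
        assert np.allclose(ratio, ratio.flat[0])

    def test_matches_scalar_formula_oracle_on_oblique_plane(self):
        geom, coords = _coords(tilt=33.0, roll=21.0, offset=(3, 4, -2))
        model = ConcomitantModel(moments=(2.0, 1.0, 0.3, 0.1))
        shape = concomitant_shape(coords, model)
        x, y, z = coords
        raw = np.empty_like(x)
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                xi, yi, zi = x[i, j], y[i, j], z[i, j]
                raw[i, j] = (2.0 * (xi**2 + yi**2) / 4 + 1.0 * zi**2
                             - 0.3 * xi * zi - 0.1 * yi * zi)
        expect = raw / np.sqrt(np.mean(raw**2))
        assert np.allclose(shape, expect, atol=1e-12)
        assert np.sqrt(np.mean(shape**2)) == pytest.approx(1.0)

    def test_zero_moments_rejected(self):
        geom, coords = _coords()
        with pytest.raises(ConfigurationError):
            concomitant_shape(coords, ConcomitantModel(moments=(0, 0, 0, 0)))


def _masks_from(geom, mask, sample):
    velocity = np.full(geom.shape, np.nan)
    velocity[mask] = sample[mask]
    return StaticMasks(global_mask=mask,
                       quiescent_mask=np.zeros_like(mask),
                       quiescent_phase_indices=np.arange(2),
                       sample_velocity=velocity)


class TestFitSurface:
    def test_noise_free_self_consistency(self):
        geom, coords = _coords(rows=48, cols=48)
        model = ConcomitantModel()
        design = design_matrix(coords, model)
        injected = np.array([0.5, 0.1, -0.2, 0.0, 0.05])
        truth_surface = design @ injected
        rng = np.random.default_rng(1)
        mask = rng.random(geom.shape) < 0.6
        fit = fit_surface(_masks_from(geom, mask, truth_surface), coords, model)
        assert np.allclose(fit.surface, truth_surface, atol=1e-9)
        expect = canonical_coefficients(design, truth_surface)
        assert np.allclose(fit.coefficients, expect, rtol=1e-8)

    def test_all_zero_samples_give_zero_surface(self):
        geom, coords = _coords()
        mask = np.ones(geom.shape, dtype=bool)
        fit = fit_surface(_masks_from(geom, mask, np.zeros(geom.shape)),
                          coords, ConcomitantModel())
        assert np.allclose(fit.coefficients, 0.0, atol=1e-12)
        assert np.allclose(fit.surface, 0.0, atol=1e-12)

    def test_surface_equals_design_times_coefficients(self):
        geom, coords = _coords()
        model = ConcomitantModel()
        rng = np.random.default_rng(2)
        mask = rng.random(geom.shape) < 0.5
        sample = rng.normal(0, 1, geom.shape)
        fit = fit_surface(_masks_from(geom, mask, sample), coords, model)
        assert np.array_equal(fit.surface,
                              design_matrix(coords, model) @ fit.coefficients)

    def test_five_term_residual_never_exceeds_linear_residual(self):
        rng = np.random.default_rng(3)
        geom, coords = _coords(rows=40, cols=40)
        model = ConcomitantModel()
        for _ in range(10):
            mask = rng.random(geom.shape) < 0.4
            sample = rng.normal(0, 1, geom.shape)
            masks = _masks_from(geom, mask, sample)
            fit5 = fit_surface(masks, coords, model)
            A = design_matrix(coords, None)[mask]
            beta, _ = solve_least_squares(A, sample[mask],
                                          expected_deficiency=1)
            rms4 = np.sqrt(np.mean((sample[mask] - A @ beta) ** 2))
            assert fit5.residual_rms <= rms4 + 1e-12

    def test_monte_carlo_unbiasedness(self):
        # 50 replicates here; the acceptance suite runs the full 200
        geom, coords = _coords(rows=48, cols=48)
        model = ConcomitantModel()
        design = design_matrix(coords, model)
        injected = canonical_coefficients(design, design @ np.array(
            [0.8, 0.05, -0.04, 0.02, 0.6]))
        truth_surface = design @ injected
        rng = np.random.default_rng(11)
        mask = np.ones(geom.shape, dtype=bool)
        estimates = []
        for _ in range(50):
            noisy = truth_surface + rng.normal(0, 1.0, geom.shape)
            fit = fit_surface(_masks_from(geom, mask, noisy), coords, model)
            estimates.append(fit.coefficients)
        est = np.array(estimates)
        bias = est.mean(axis=0) - injected
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(bias) < 4 * se + 1e-12)

    def test_too_few_samples_rejected(self):
        geom, coords = _coords()
        mask = np.zeros(geom.shape, dtype=bool)
        mask[0, :4] = True
        from pccor.core import StructuralError
        with pytest.raises(StructuralError):
            fit_surface(_masks_from(geom, mask, np.zeros(geom.shape)),
                        coords, ConcomitantModel())


class TestSolver:
    def test_matches_normal_equations_on_well_conditioned_problems(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            A = np.column_stack([np.ones(60), rng.normal(0, 1, (60, 3))])
            y = rng.normal(0, 1, 60)
            beta, dropped = solve_least_squares(A, y)
            assert dropped == ()
            oracle = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose(beta, oracle, atol=1e-10)

    def test_duplicate_column_dropped_with_zero_coefficient(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 50)
        A = np.column_stack([np.ones(50), base, base.copy(),
                             rng.normal(0, 1, 50)])
        y = rng.normal(0, 1, 50)
        with pytest.warns(UserWarning, match="rank-deficient"):
            beta, dropped = solve_least_squares(A, y)
        assert len(dropped) == 1
        assert beta[dropped[0]] == 0.0


class TestGuard:
    def _fit_with_surface(self, surface):
        from pccor.background import FitResult
        return FitResult(coefficients=np.zeros(5), surface=surface,
                         n_samples=100, residual_rms=0.0)

    def test_zero_surface_withholds_correction(self, params):
        geom, _ = _coords()
        fit = self._fit_with_surface(np.zeros(geom.shape))
        assert overfit_guard(fit, geom, params) is False
        assert fit.guard_triggered is True

    def test_constant_surface_above_threshold_applies(self, params):
        geom, _ = _coords()
        fit = self._fit_with_surface(np.full(geom.shape, 1.0))
        assert overfit_guard(fit, geom, params) is True

    def test_sign_alternating_surface_uses_mean_absolute_value(self, params):
        geom, _ = _coords()
        surface = np.fromfunction(lambda i, j: 0.3 * (-1.0) ** (i + j),
                                  geom.shape)
        fit = self._fit_with_surface(surface)
        assert overfit_guard(fit, geom, params) is False
        # exhaustive ROI oracle
        roi = fov_center_roi(geom, params.guard_roi_radius)
        assert fit.diagnostics["guard_roi_mean_cm_s"] == pytest.approx(
            np.abs(surface[roi]).mean())


class TestCorrections:
    def test_zero_surface_is_identity(self, nominal_scene):
        in_vivo, _, _ = nominal_scene
        from pccor.background import FitResult
        fit = FitResult(coefficients=np.zeros(5),
                        surface=np.zeros(in_vivo.geometry.shape),
                        n_samples=10, residual_rms=0.0)
        out = apply_correction(in_vivo, fit)
        assert np.array_equal(out.velocity, in_vivo.velocity)

    def test_conservation_identity_to_machine_precision(self, nominal_scene):
        # float subtraction is invertible only to rounding error (~1 ulp)
        in_vivo, _, _ = nominal_scene
        rng = np.random.default_rng(8)
        from pccor.background import FitResult
        surface = rng.normal(0, 1, in_vivo.geometry.shape)
        fit = FitResult(coefficients=np.zeros(5), surface=surface,
                        n_samples=10, residual_rms=0.0)
        out = apply_correction(in_vivo, fit)
        np.testing.assert_allclose(out.velocity + surface[None],
                                   in_vivo.velocity, rtol=0, atol=1e-12)

    def test_guard_skip_returns_input_unchanged(self, nominal_scene):
        in_vivo, _, _ = nominal_scene
        from pccor.background import FitResult
        fit = FitResult(coefficients=np.zeros(5),
                        surface=np.ones(in_vivo.geometry.shape),
                        n_samples=10, residual_rms=0.0)
        out = apply_correction(in_vivo, fit, apply=False)
        assert out is in_vivo

    def test_noise_free_background_cancels_exactly(self, clean_scene, params):
        in_vivo, _, truth = clean_scene
        masks = build_static_masks(in_vivo, params)
        coords = plane_coordinates(in_vivo.geometry)
        fit = fit_surface(masks, coords, ConcomitantModel())
        corrected = apply_correction(in_vivo, fit)
        resid = corrected.velocity.mean(axis=0)[truth.static_mask]
        assert np.max(np.abs(resid)) < 1e-8

    def test_linear_correction_removes_planar_offset_exactly(self):
        cfg = PhantomConfig(seed=4, background_coeffs=(1.0, 0.08, -0.06, 0, 0),
                            noise_sd=0.0, contamination=0.0,
                            magnitude_noise_sd=0.0, air_noise_fraction=0.0)
        in_vivo, _, truth = generate(cfg)
        masks = build_static_masks(in_vivo)
        coords = plane_coordinates(in_vivo.geometry)
        corrected, fit = linear_correction(in_vivo, masks, coords)
        resid = corrected.velocity.mean(axis=0)[truth.static_mask]
        assert np.max(np.abs(resid)) < 1e-8

    def test_concomitant_offset_defeats_linear_but_not_five_term(self):
        cfg = PhantomConfig(seed=5, background_coeffs=(0, 0, 0, 0, 1.5),
                            noise_sd=0.0, contamination=0.0,
                            magnitude_noise_sd=0.0, air_noise_fraction=0.0)
        in_vivo, _, truth = generate(cfg)
        masks = build_static_masks(in_vivo)
        coords = plane_coordinates(in_vivo.geometry)
        _, fit_lin = linear_correction(in_vivo, masks, coords)
        fit_5 = fit_surface(masks, coords, ConcomitantModel())
        assert fit_lin.residual_rms > 10 * fit_5.residual_rms
        assert fit_lin.residual_rms > 1e-6

    def test_phantom_zero_offset_is_identity(self, clean_scene):
        in_vivo, _, _ = clean_scene
        phantom = in_vivo.with_velocity(np.zeros_like(in_vivo.velocity))
        out = phantom_correction(in_vivo, phantom)
        assert np.array_equal(out.velocity, in_vivo.velocity)

    def test_phantom_subtraction_conserves(self, clean_scene):
        in_vivo, phantom, _ = clean_scene
        out = phantom_correction(in_vivo, phantom)
        offset = phantom.velocity.mean(axis=0)
        np.testing.assert_allclose(out.velocity + offset[None],
                                   in_vivo.velocity, rtol=0, atol=1e-12)

    def test_correction_is_linear_in_velocity_scale(self, clean_scene, params):
        in_vivo, _, _ = clean_scene
        masks = build_static_masks(in_vivo, params)
        coords = plane_coordinates(in_vivo.geometry)
        fit1 = fit_surface(masks, coords, ConcomitantModel())
        scaled = in_vivo.with_velocity(in_vivo.velocity * 2.0)
        masks2 = build_static_masks(scaled, params)
        fit2 = fit_surface(masks2, coords, ConcomitantModel())
        assert np.allclose(fit2.surface, 2.0 * fit1.surface, atol=1e-9)
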