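"""Fractal-dimension estimation: OLS fit, t-intervals, regime detection."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from flocscatter import (DomainError, FractalDimensionEstimator,
                         InsufficientDataError, NoRegimeError, OpticalConfig,
                         PowerLawFit, QGrid, RegimeBounds, ScatteringCurve,
                         detect_power_law_regime, fd_pipeline,
                         fit_power_law, fractal_intensity,
                         generate_scattering_sample, guinier_intensity,
                         q_to_diameter, rgd_validity_flag, simulate_measurement,
                         student_t_ci)
from tests.conftest import GRID_STEP_FACTOR


def full_bounds(curve):
    return RegimeBounds(curve.q[0], curve.q[-1], len(curve.grid))


class TestFitPowerLaw:
    def test_exact_power_law_recovered_to_machine_precision(self):
        grid = QGrid.logspace(1e-2, 1e1, 200)
        curve = ScatteringCurve(grid, fractal_intensity(grid.q, 2.28))
        fit = fit_power_law(curve, full_bounds(curve))
        assert fit.slope == pytest.approx(-2.28, abs=1e-10)
        assert fit.slope_stderr == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_gives_zero_slope(self, default_grid):
        curve = ScatteringCurve(default_grid,
                                np.full(len(default_grid), 3.7))
        fit = fit_power_law(curve, full_bounds(curve))
        assert fit.slope == 0.0
        assert fit.slope_stderr == 0.0

    def test_three_point_fit_matches_hand_computed_ols(self):
        # log10 q = {0, 1, 2}, log10 I = {0, -2, -4.3}:
        # slope = -2.15, intercept = 0.05, SSE = 0.015 on 1 dof,
        # stderr = sqrt(0.015 / Sxx) = sqrt(0.0075)
        curve = ScatteringCurve(QGrid(np.array([1.0, 10.0, 100.0])),
                                10.0 ** np.array([0.0, -2.0, -4.3]))
        fit = fit_power_law(curve, full_bounds(curve))
        assert fit.slope == pytest.approx(-2.15, abs=1e-12)
        assert fit.intercept == pytest.approx(0.05, abs=1e-12)
        assert fit.slope_stderr == pytest.approx(math.sqrt(0.0075),
                                                 rel=1e-10)

    def test_too_few_points_in_window(self, power_law_curve):
        with pytest.raises(InsufficientDataError):
            fit_power_law(power_law_curve,
                          RegimeBounds(1.0, 1.06, 3))

    def test_scale_invariance_of_slope_and_stderr(self, default_grid, rng):
        base = fractal_intensity(default_grid.q, 2.1)
        noisy = base * np.exp(0.01 * rng.standard_normal(base.size))
        c1 = ScatteringCurve(default_grid, noisy)
        c2 = ScatteringCurve(default_grid, 137.0 * noisy)
        f1 = fit_power_law(c1, full_bounds(c1))
        f2 = fit_power_law(c2, full_bounds(c2))
        assert f1.slope == pytest.approx(f2.slope, abs=1e-12)
        assert f1.slope_stderr == pytest.approx(f2.slope_stderr, rel=1e-9)


class TestStudentTCI:
    def test_zero_stderr_gives_zero_halfwidth(self):
        fit = PowerLawFit(-2.2, 0.0, 0.0, 1.0, 50)
        assert student_t_ci(fit, 0.95) == 0.0

    def test_n4_halfwidth_from_independent_t_table(self):
        # t_{0.975, 2} = 4.302652729911...
        fit = PowerLawFit(-2.0, 0.0, 0.01, 0.999, 4)
        assert student_t_ci(fit, 0.95) == pytest.approx(0.0430265,
                                                        abs=1e-6)

    def test_halfwidth_increases_with_level(self):
        fit = PowerLawFit(-2.0, 0.0, 0.01, 0.999, 30)
        widths = [student_t_ci(fit, lv) for lv in (0.80, 0.90, 0.95, 0.99)]
        assert np.all(np.diff(widths) > 0)

    def test_bad_level_rejected(self):
        fit = PowerLawFit(-2.0, 0.0, 0.01, 0.999, 30)
        with pytest.raises(DomainError):
            student_t_ci(fit, 1.0)

    def test_halfwidth_shrinks_like_inverse_sqrt_n(self):
        """Mean CI halfwidth over a fixed-noise ensemble scales ~ 1/sqrt(n)
        at fixed q-range (within 20% over an 8x range of n)."""
        def mean_halfwidth(n, seeds=80):
            grid = QGrid.logspace(0.1, 10, n)
            base = ScatteringCurve(grid, fractal_intensity(grid.q, 2.2))
            out = []
            for s in range(seeds):
                noisy = simulate_measurement(base, 0.02, n_reps=1, seed=s)
                fit = fit_power_law(noisy, full_bounds(noisy))
                out.append(student_t_ci(fit, 0.95))
            return float(np.mean(out))

        ratio = mean_halfwidth(25) / mean_halfwidth(200)
        assert ratio == pytest.approx(math.sqrt(8), rel=0.20)


class TestRegimeDetection:
    def test_exact_power_law_selects_full_grid(self, power_law_curve):
        b = detect_power_law_regime(power_law_curve)
        assert b.q_low == power_law_curve.q[0]
        assert b.q_high == power_law_curve.q[-1]
        assert b.n_points == len(power_law_curve.grid)

    def test_composite_bounds_recover_ground_truth_crossovers(
            self, composite_curve):
        """Detected bounds land within one grid step of 1/a and 1/Rp."""
        b = detect_power_law_regime(composite_curve)
        assert b.q_low / 0.05 < GRID_STEP_FACTOR
        assert 0.05 / b.q_low < GRID_STEP_FACTOR
        assert b.q_high / 2.0 < GRID_STEP_FACTOR
        assert 2.0 / b.q_high < GRID_STEP_FACTOR

    def test_pure_guinier_curve_has_no_regime(self):
        rg = 50.0
        grid = QGrid(np.logspace(-3, math.log10(0.9 / rg), 60))
        curve = ScatteringCurve(grid, guinier_intensity(grid.q, rg))
        with pytest.raises(NoRegimeError):
            detect_power_law_regime(curve)

    def test_porod_branch_rejected_as_fractal_regime(self, default_grid):
        curve = ScatteringCurve(default_grid,
                                fractal_intensity(default_grid.q, 4.0))
        with pytest.raises(NoRegimeError):
            detect_power_law_regime(curve)

    def test_detection_is_idempotent(self):
        curve, _ = generate_scattering_sample(df=2.2, seed=5)
        b1 = detect_power_law_regime(curve)
        b2 = detect_power_law_regime(curve.restrict(b1.q_low, b1.q_high))
        assert b1 == b2

    def test_min_points_floor_enforced(self, power_law_curve):
        with pytest.raises(DomainError):
            detect_power_law_regime(power_law_curve, min_points=4)


class TestQToDiameter:
    def test_reciprocal_conversion(self):
        assert q_to_diameter(0.1) == pytest.approx(10.0)

    def test_round_trip(self):
        for d in (0.8, 30.0, 245.7):
            assert q_to_diameter(1.0 / d) == pytest.approx(d, rel=1e-12)

    def test_bound_pair_maps_to_diameter_range(self):
        assert q_to_diameter(1.0 / 30.0) == pytest.approx(30.0)
        assert q_to_diameter(1.0 / 0.8) == pytest.approx(0.8)

    def test_two_pi_convention_opt_in(self):
        assert q_to_diameter(1.0, convention="2pi") == pytest.approx(
            2 * math.pi)

    def test_nonpositive_q_rejected(self):
        with pytest.raises(DomainError):
            q_to_diameter(0.0)


class TestRGDFlag:
    def test_submicron_valid(self):
        assert rgd_validity_flag(0.1) is True

    def test_thirty_micron_invalid(self):
        assert rgd_validity_flag(30.0) is False

    def test_boundary_is_strict(self):
        optics = OpticalConfig()
        assert rgd_validity_flag(optics.wavelength_um, optics) is False


class TestPipeline:
    def test_noiseless_composite_recovers_generating_df(self):
        curve, _ = generate_scattering_sample(df=2.26, noise_sd=0.0)
        res = fd_pipeline(curve)
        assert res.fd == pytest.approx(2.26, abs=1e-3)

    def test_diameter_range_is_reciprocal_of_own_bounds(self):
        curve, _ = generate_scattering_sample(df=2.1, seed=3)
        res = fd_pipeline(curve)
        assert res.d_min_um == pytest.approx(1.0 / res.bounds.q_high)
        assert res.d_max_um == pytest.approx(1.0 / res.bounds.q_low)
        assert res.d_min_um < res.d_max_um

    def test_regime_beyond_wavelength_sets_rgd_flag(self):
        # regime reaches d_max = a = 25 um >> lambda = 0.6328 um
        curve, _ = generate_scattering_sample(df=2.2, noise_sd=0.0)
        res = fd_pipeline(curve)
        assert res.exceeds_rgd is True
        assert res.d_max_um > res.rgd_valid_up_to_um

    def test_fd_and_ci_invariant_to_curve_scaling(self):
        curve, _ = generate_scattering_sample(df=2.3, seed=11)
        scaled = ScatteringCurve(curve.grid, 1e4 * curve.intensity)
        r1, r2 = fd_pipeline(curve), fd_pipeline(scaled)
        assert r1.fd == pytest.approx(r2.fd, abs=1e-12)
        assert r1.ci_halfwidth == pytest.approx(r2.ci_halfwidth, rel=1e-9)

    def test_fd_outside_physical_range_warns_not_raises(self, default_grid):
        curve = ScatteringCurve(default_grid,
                                fractal_intensity(default_grid.q, 3.4))
        with pytest.warns(UserWarning, match="outside"):
            res = fd_pipeline(curve)
        assert res.fd == pytest.approx(3.4, abs=1e-9)

    def test_recovery_across_observed_df_span(self):
        """Median |fd - truth| < 0.02 and max < 0.05 over the observed
        exponent span with default noise, 52 seeds."""
        errs = []
        for df in (1.98, 2.07, 2.20, 2.34):
            for seed in range(13):
                curve, truth = generate_scattering_sample(df=df, seed=seed)
                errs.append(abs(fd_pipeline(curve).fd - truth["df"]))
        errs = np.asarray(errs)
        assert np.median(errs) < 0.02
        assert errs.max() < 0.05


class TestEstimatorAPI:
    def test_fit_exposes_result_attributes(self):
        curve, truth = generate_scattering_sample(df=2.26, seed=7)
        est = FractalDimensionEstimator().fit(curve.q, curve.intensity)
        assert abs(est.fd_ - truth["df"]) < 0.05
        assert est.ci_halfwidth_ <= 0.05
        assert est.q_low_ < est.q_high_
        assert est.d_min_um_ == pytest.approx(1.0 / est.q_high_)
        assert est.exceeds_rgd_ is True
        assert est.result_.fd == est.fd_

    def test_fit_accepts_curve_object(self):
        curve, _ = generate_scattering_sample(df=2.1, seed=2)
        est = FractalDimensionEstimator().fit(curve)
        assert est.n_points_ >= 8

    def test_predict_evaluates_fitted_power_law(self, power_law_curve):
        est = FractalDimensionEstimator().fit(power_law_curve)
        q = np.array([0.5, 1.0, 2.0])
        np.testing.assert_allclose(est.predict(q),
                                   10.0 ** est.intercept_ * q ** est.slope_)

    def test_sklearn_clone_round_trips_params(self):
        est = FractalDimensionEstimator(r2_min=0.99, slope_tol=0.2,
                                        level=0.9)
        params = clone(est).get_params()
        assert params["r2_min"] == 0.99
        assert params["slope_tol"] == 0.2
        assert params["level"] == 0.9

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            FractalDimensionEstimator().predict([1.0])
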