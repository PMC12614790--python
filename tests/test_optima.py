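"""Tests for the closed-form and numerical optimizers and their agreement."""

from dataclasses import replace

import numpy as np
import pytest

from attract_choice import (
    AttractionParams,
    ModelBConfig,
    ParameterError,
    PatchState,
    argmax_attraction_p,
    facilitation_threshold,
    model_b_stationarity_residual,
    model_b_yield,
    optimal_p_numeric,
    optimal_w_analytic,
    optimal_w_numeric,
    tangent_residual,
    visit_rates,
    w_star_curve,
)


class TestTangentCondition:
    def test_hand_worked_zero_at_optimum(self, hyper_params):
        """dN/dw = 10*0.4/1.6^2 = 1.5625 equals N/(c+w) = 17.5/11.2 at w = 1.2."""
        assert tangent_residual(hyper_params, c=10.0, w=1.2) == pytest.approx(0.0, abs=1e-12)

    def test_negative_far_beyond_optimum(self, hyper_params):
        assert tangent_residual(hyper_params, c=10.0, w=1e4) < 0

    def test_zero_at_analytic_optimum(self, hyper_params):
        res = optimal_w_analytic(hyper_params, c=25.0)
        assert not res.at_boundary
        assert abs(res.residual) < 1e-9

    def test_finite_difference_fallback_matches_closed_form(self, hyper_params):
        fd = tangent_residual(hyper_params, c=10.0, w=2.0, form="exponential_saturating")
        # independent closed form for the saturating family
        N = 10.0 * (1 - np.exp(-2.0 / 0.4)) + 10.0
        closed = 10.0 / 0.4 * np.exp(-2.0 / 0.4) - N / 12.0
        assert fd == pytest.approx(closed, abs=1e-6)


class TestAnalyticOptimum:
    def test_hand_solved_quadratic(self, hyper_params):
        """20 w^2 + 8 w - 38.4 = 0 has positive root w = 1.2."""
        res = optimal_w_analytic(hyper_params, c=10.0)
        assert res.location == pytest.approx(1.2)
        assert res.objective == pytest.approx(15.625)
        assert not res.at_boundary

    def test_no_crop_pool_reduces_to_sqrt(self):
        """With N_c = 0 the quadratic is A w^2 = A a c, so w* = sqrt(a*c)."""
        params = AttractionParams(A=10.0, a=0.4, N_c=0.0)
        res = optimal_w_analytic(params, c=10.0)
        assert res.location == pytest.approx(2.0)

    def test_boundary_at_threshold(self, hyper_params):
        c0 = facilitation_threshold(hyper_params)
        res = optimal_w_analytic(hyper_params, c=c0)
        assert res.location == 0.0
        assert res.at_boundary

    def test_interior_just_above_threshold(self, hyper_params):
        c0 = facilitation_threshold(hyper_params)
        res = optimal_w_analytic(hyper_params, c=c0 * 1.01)
        assert res.location > 0.0
        assert not res.at_boundary

    def test_facilitation_gain_at_optimum(self, hyper_params):
        """For c > c0, F(c, w*) strictly exceeds the no-wildflower baseline N_c."""
        res = optimal_w_analytic(hyper_params, c=10.0)
        assert res.objective > hyper_params.N_c


class TestFacilitationThreshold:
    def test_printed_formula(self, hyper_params):
        assert facilitation_threshold(hyper_params) == pytest.approx(0.4)

    def test_zero_when_no_crop_pool(self):
        assert facilitation_threshold(AttractionParams(A=5.0, a=1.0, N_c=0.0)) == 0.0

    def test_undefined_without_wildflower_attraction(self):
        with pytest.raises(ZeroDivisionError):
            facilitation_threshold(AttractionParams(A=0.0, a=1.0, N_c=1.0))


class TestNumericOptimum:
    def test_matches_analytic(self, hyper_params):
        res = optimal_w_numeric("hyperbolic", hyper_params, c=10.0, w_max=50.0)
        assert res.location == pytest.approx(1.2, abs=1e-6)

    def test_flat_objective_reports_left_boundary(self):
        res = optimal_w_numeric("linear_additive", AttractionParams(g=1.0), c=10.0)
        assert res.location == 0.0
        assert res.at_boundary

    def test_decreasing_objective_reports_zero(self):
        res = optimal_w_numeric("linear_plus_local", AttractionParams(L=10.0, g=1.0), c=10.0)
        assert res.location == 0.0
        assert res.at_boundary

    def test_warns_when_window_too_small(self):
        params = AttractionParams(A=10.0, a=0.4, N_c=10.0)
        with pytest.warns(UserWarning, match="upper search limit"):
            optimal_w_numeric("hyperbolic", params, c=10.0, w_max=0.5)

    def test_invalid_inputs(self, hyper_params):
        with pytest.raises(ParameterError):
            optimal_w_numeric("hyperbolic", hyper_params, c=1.0, w_max=-1.0)
        with pytest.raises(ParameterError):
            optimal_w_numeric("hyperbolic", hyper_params, c=1.0, tol=0.0)


class TestOracleEquivalence:
    def test_closed_form_agrees_with_brute_force(self, rng):
        """200 random hyperbolic draws: analytic w* vs grid+refinement oracle.

        Locations agree to 1e-5 absolute; boundary classification (w*=0
        iff c <= c0 = N_c*a/A) is consistent across every draw.
        """
        n_interior = 0
        for _ in range(200):
            params = AttractionParams(
                A=rng.uniform(0.1, 20.0),
                a=rng.uniform(0.05, 5.0),
                N_c=rng.uniform(0.0, 20.0),
            )
            c = rng.uniform(0.01, 50.0)
            ana = optimal_w_analytic(params, c)
            num = optimal_w_numeric("hyperbolic", params, c, w_max=50.0)
            assert num.location == pytest.approx(ana.location, abs=1e-5)
            if ana.at_boundary:
                assert num.location <= 1e-5
            if num.at_boundary:
                assert ana.location <= 1e-5
            # threshold property
            c0 = facilitation_threshold(params)
            assert (ana.location > 0) == (c > c0)
            if not ana.at_boundary:
                n_interior += 1
                assert ana.objective == pytest.approx(num.objective, rel=1e-9)
        assert n_interior > 50  # the draw ranges exercise both regimes


class TestWStarCurve:
    def test_zero_below_threshold(self, hyper_params):
        c0 = facilitation_threshold(hyper_params)
        table = w_star_curve(hyper_params, np.linspace(0.0, c0, 9))
        assert np.all(table["w_star"].to_numpy() == 0.0)

    def test_sqrt_law_without_crop_pool(self):
        params = AttractionParams(A=10.0, a=0.4, N_c=0.0)
        table = w_star_curve(params, [1.0, 4.0, 9.0])
        assert table["w_star"].to_numpy() == pytest.approx(np.sqrt([0.4, 1.6, 3.6]))

    def test_monotone_nondecreasing_strict_above_threshold(self, hyper_params, rng):
        c0 = facilitation_threshold(hyper_params)
        grid = np.sort(rng.uniform(0.0, 30.0, 60))
        table = w_star_curve(hyper_params, grid)
        w = table["w_star"].to_numpy()
        assert np.all(np.diff(w) >= 0)
        above = grid > c0 * (1 + 1e-9)
        w_above = w[above]
        assert np.all(np.diff(w_above) > 0)

    def test_rejects_descending_grid(self, hyper_params):
        with pytest.raises(ParameterError):
            w_star_curve(hyper_params, [2.0, 1.0])


class TestFixedAreaOptimum:
    def test_crop_yield_peak_rounds_to_five_percent(self, symmetric_area_config):
        res = optimal_p_numeric(symmetric_area_config)
        assert not res.at_boundary
        assert round(res.location, 2) == pytest.approx(0.05)

    def test_attraction_peaks_at_half_by_symmetry(self, symmetric_area_config):
        res = argmax_attraction_p(symmetric_area_config)
        assert res.location == pytest.approx(0.5, abs=1e-6)

    def test_yield_optimum_left_of_attraction_optimum(self, symmetric_area_config):
        """Paying for wildflower area pulls p* below the attraction peak."""
        p_star = optimal_p_numeric(symmetric_area_config).location
        n_star = argmax_attraction_p(symmetric_area_config).location
        assert p_star < n_star

    def test_attractive_wildflowers_shift_attraction_peak_up(self, attractive_wild_config):
        assert argmax_attraction_p(attractive_wild_config).location > 0.5

    def test_only_crop_attracts(self):
        cfg = ModelBConfig(p=0.0, params=AttractionParams(A_w=0.0, A_c=1.0, a_w=0.4, a_c=0.4))
        res = argmax_attraction_p(cfg)
        assert res.location == 0.0
        assert res.at_boundary

    def test_worthless_wildflowers_give_zero_area(self, symmetric_area_config):
        cfg = replace(symmetric_area_config, b=1e-9)
        res = optimal_p_numeric(cfg)
        assert res.location == pytest.approx(0.0, abs=1e-6)
        assert res.at_boundary

    def test_more_attractive_wildflowers_raise_optimal_yield(
        self, symmetric_area_config, attractive_wild_config
    ):
        f_low = optimal_p_numeric(symmetric_area_config).objective
        f_high = optimal_p_numeric(attractive_wild_config).objective
        assert f_high > f_low

    def test_stationarity_residual_vanishes_at_optimum(self, symmetric_area_config):
        res = optimal_p_numeric(symmetric_area_config)
        r = model_b_stationarity_residual(replace(symmetric_area_config, p=res.location))
        assert abs(r) < 1e-6

    def test_residual_changes_sign_across_optimum(self, symmetric_area_config):
        res = optimal_p_numeric(symmetric_area_config)
        lo = model_b_stationarity_residual(replace(symmetric_area_config, p=res.location - 0.01))
        hi = model_b_stationarity_residual(replace(symmetric_area_config, p=res.location + 0.01))
        assert lo > 0 > hi

    def test_finite_difference_matches_closed_form(self, symmetric_area_config):
        cfg = replace(symmetric_area_config, p=0.3)
        closed = model_b_stationarity_residual(cfg, closed_form=True)
        fd = model_b_stationarity_residual(cfg, closed_form=False)
        assert fd == pytest.approx(closed, abs=1e-6)

    def test_residual_domain(self, symmetric_area_config):
        with pytest.raises(ParameterError):
            model_b_stationarity_residual(replace(symmetric_area_config, p=0.0))

    def test_total_area_scales_objective_not_location(self, symmetric_area_config):
        scaled = replace(symmetric_area_config, total_area=7.0)
        base = optimal_p_numeric(symmetric_area_config)
        res = optimal_p_numeric(scaled)
        assert res.location == pytest.approx(base.location, abs=1e-6)
        assert res.objective == pytest.approx(7.0 * base.objective)
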