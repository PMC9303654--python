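import math

import numpy as np
import pytest

from twostage.consistent import (
    InfeasibleError,
    design_conditional_rejection,
    recalc_not_worse,
    recalc_reoptimize,
    run_scenario,
    solve_matched,
)
from twostage.monitoring import conditional_power, predictive_power_curve
from twostage.naive import conditional_error
from twostage.priors import InterimState, point_prior, truncated_normal_prior


@pytest.fixture(scope="module")
def phi():
    return point_prior(0.4)


class TestSolveMatched:
    def test_residuals_of_matched_solution(self, planning_prior):
        m, z_m, ce, pp = 26, 0.8, 0.05, 0.85
        n_new, c_new = solve_matched(m, z_m, ce, pp, planning_prior)
        assert conditional_power(m, n_new, z_m, c_new, 0.0) == pytest.approx(
            ce, abs=1e-10
        )
        achieved = predictive_power_curve(planning_prior, m, np.array([z_m]),
                                          n_new, c_new)[0]
        assert achieved == pytest.approx(pp, abs=1e-8)

    def test_current_design_is_fixed_point_by_construction(self, planning_prior):
        m, z_m, n0, c0 = 26, 1.0, 90.0, 2.05
        ce = float(conditional_error(m, n0, z_m, c0))
        pp = float(predictive_power_curve(planning_prior, m, np.array([z_m]),
                                          n0, c0)[0])
        n_new, c_new = solve_matched(m, z_m, ce, pp, planning_prior)
        assert n_new == pytest.approx(n0, rel=1e-8)
        assert c_new == pytest.approx(c0, abs=1e-8)

    def test_unreachable_target_reported_infeasible(self, planning_prior):
        with pytest.raises(InfeasibleError) as exc:
            solve_matched(26, 0.0, 0.02, 0.999999, planning_prior, n_cap=200)
        assert exc.value.pp_range is not None

    def test_parameter_validation(self, planning_prior):
        with pytest.raises(ValueError):
            solve_matched(26, 0.0, 1.5, 0.8, planning_prior)
        with pytest.raises(ValueError):
            solve_matched(26, 0.0, 0.05, 0.0, planning_prior)


class TestNotWorse:
    def test_unchanged_prior_is_fixed_point(self, gsd_result, phi):
        d = gsd_result.design
        m = round(d.m)
        for z in np.linspace(d.z_futility + 0.1, d.z_efficacy - 0.1, 20):
            n_new, c_new = recalc_not_worse(d, InterimState(m, float(z)), phi, phi)
            assert n_new == pytest.approx(float(d.n_of(z)), rel=1e-3)
            assert c_new == pytest.approx(float(d.c_of(z)), abs=1e-4)

    def test_fixed_point_on_spline_design(self, optimal_result, planning_prior):
        """Consistency also holds for the free-function optimal design."""
        d = optimal_result.design
        m = round(d.m)
        for z in np.linspace(d.z_futility + 0.1, d.z_efficacy - 0.1, 7):
            n_new, c_new = recalc_not_worse(d, InterimState(m, float(z)),
                                            planning_prior, planning_prior)
            assert n_new == pytest.approx(float(d.n_of(z)), rel=1e-3)
            assert c_new == pytest.approx(float(d.c_of(z)), abs=1e-4)

    def test_optimistic_revision_shrinks_sample_size(self, gsd_result, phi):
        d = gsd_result.design
        m = round(d.m)
        psi = point_prior(0.45)
        for z in (0.5, 1.0, 1.8):
            n_new, _ = recalc_not_worse(d, InterimState(m, z), phi, psi)
            assert n_new <= float(d.n_of(z)) + 1e-9

    def test_conditional_error_never_exceeded(self, gsd_result, phi):
        d = gsd_result.design
        m = round(d.m)
        for psi in (point_prior(0.3), point_prior(0.5),
                    truncated_normal_prior(0.35, 0.1, -0.5, 1.0)):
            for z in (0.4, 1.2, 2.0):
                n_new, c_new = recalc_not_worse(d, InterimState(m, z), phi, psi)
                ce0 = float(conditional_power(d.m, float(d.n_of(z)), z,
                                              float(d.c_of(z)), 0.0))
                assert float(conditional_power(m, n_new, z, c_new, 0.0)) \
                    <= ce0 + 1e-8

    def test_drifts_from_power_target_under_switched_prior(self, gsd_result, phi):
        sc = run_scenario(gsd_result.design, "not_worse",
                          lambda z: point_prior(0.35), eval_theta=0.35,
                          old_prior=phi)
        assert abs(sc.expected_power - 0.8) > 0.005


class TestOffScheduleLook:
    def test_reduces_to_design_conditional_power_at_planned_interim(self, gsd_result):
        d = gsd_result.design
        m = round(d.m)
        val = design_conditional_rejection(d, m, 1.0, 0.0)
        assert val == pytest.approx(
            float(conditional_power(d.m, float(d.n_of(1.0)), 1.0,
                                    float(d.c_of(1.0)), 0.0)), rel=1e-12)

    def test_earlier_look_monotone_in_interim_statistic(self, gsd_result):
        d = gsd_result.design
        vals = [design_conditional_rejection(d, round(d.m) - 8, z, 0.0)
                for z in (-1.0, 0.0, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_off_schedule_recalc_controls_conditional_error(self, gsd_result, phi):
        d = gsd_result.design
        m_prime = round(d.m) - 8
        z = 0.9
        n_new, c_new = recalc_not_worse(d, InterimState(m_prime, z), phi, phi)
        ce0 = design_conditional_rejection(d, m_prime, z, 0.0)
        assert float(conditional_power(m_prime, n_new, z, c_new, 0.0)) \
            == pytest.approx(ce0, abs=1e-8)


class TestReoptimize:
    def test_unchanged_prior_is_fixed_point(self, gsd_result, phi):
        d = gsd_result.design
        m = round(d.m)
        cache = {}
        for z in np.linspace(0.1, d.z_efficacy - 0.1, 20):
            n_new, c_new = recalc_reoptimize(d, InterimState(m, float(z)), phi, phi,
                                             0.025, 0.8, _step1_cache=cache)
            assert n_new == pytest.approx(float(d.n_of(z)), rel=1e-3)
            assert c_new == pytest.approx(float(d.c_of(z)), abs=1e-4)

    @pytest.mark.parametrize("theta1_new", [0.35, 0.45])
    def test_data_independent_switch_preserves_power(self, gsd_result, phi,
                                                     theta1_new):
        """The two-step rule keeps the unconditional expected power at the
        0.8 target when the prior revision does not depend on the data."""
        psi = point_prior(theta1_new)
        sc = run_scenario(gsd_result.design, "reoptimize", lambda z: psi,
                          eval_theta=theta1_new, old_prior=phi)
        assert sc.expected_power == pytest.approx(0.8, abs=0.005)

    def test_response_adaptive_update_breaks_power_guarantee(self, gsd_result, phi):
        m = round(gsd_result.design.m)

        def heuristic(z):
            return point_prior((z / math.sqrt(m) + 0.4) / 2.0)

        sc = run_scenario(gsd_result.design, "reoptimize", heuristic,
                          eval_theta=0.4, old_prior=phi)
        assert abs(sc.expected_power - 0.8) > 0.005


class TestScenarios:
    def test_fixed_threshold_rule_is_most_extreme(self, gsd_result, phi):
        d = gsd_result.design
        psi = point_prior(0.35)
        z_grid = np.linspace(d.z_futility + 1e-6, d.z_efficacy - 1e-6, 41)
        n_orig = 4.0 * np.asarray(d.n_of(z_grid))
        devs = {}
        for rule in ("pp_ge", "not_worse", "reoptimize"):
            sc = run_scenario(d, rule, lambda z: psi, eval_theta=0.35,
                              old_prior=phi)
            devs[rule] = float(np.max(np.abs(sc.curves.n_total.values - n_orig)))
        assert devs["pp_ge"] > devs["not_worse"]
        assert devs["pp_ge"] > devs["reoptimize"]

    def test_unchanged_prior_leaves_curves_untouched(self, gsd_result, phi):
        d = gsd_result.design
        sc = run_scenario(d, "not_worse", lambda z: phi, eval_theta=0.4,
                          old_prior=phi, n_total_range=(4 * d.m + 1, 4000))
        expected = 4.0 * np.asarray(d.n_of(sc.curves.z_m.values))
        np.testing.assert_allclose(sc.curves.n_total.values, expected, rtol=1e-6)

    def test_heuristic_update_hits_the_cap(self, gsd_result, phi):
        m = round(gsd_result.design.m)

        def heuristic(z):
            return point_prior((z / math.sqrt(m) + 0.4) / 2.0)

        sc = run_scenario(gsd_result.design, "pp_ge", heuristic, eval_theta=0.4,
                          old_prior=phi)
        at_cap = sc.curves.n_total.values >= 400.0 - 1e-6
        assert at_cap.mean() > 0.2  # cap binds on a substantial z-interval
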