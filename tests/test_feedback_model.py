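"""Unit and property tests for the autoregulation steady-state model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoreg import feedback_model as fm
from autoreg.feedback_model import (
    INFINITE_N,
    CategoryResult,
    HillSolution,
    ModelParams,
    NoAdmissibleSolution,
)


def bisect_steady_state(p, tol=1e-12):
    """Independent bisection oracle for the Hill steady state."""

    def residual(m):
        return p.c * p.beta * p.K**p.n / (m**p.n + p.K**p.n) - p.gamma * m

    lo, hi = 0.0, p.c * p.beta / p.gamma
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


finite_params = st.builds(
    ModelParams,
    beta=st.floats(0.1, 10.0),
    gamma=st.floats(0.1, 10.0),
    K=st.floats(0.05, 10.0),
    n=st.floats(0.5, 40.0),
    c=st.sampled_from([1, 2]),
)


class TestModelParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(beta=1, gamma=0, K=1, n=4, c=2)
        with pytest.raises(ValueError):
            ModelParams(beta=1, gamma=1, K=-1, n=4, c=2)
        with pytest.raises(ValueError):
            ModelParams(beta=1, gamma=1, K=1, n=0, c=2)
        with pytest.raises(ValueError):
            ModelParams(beta=1, gamma=1, K=1, n=4, c=3)

    def test_json_round_trip_finite_n(self):
        p = ModelParams(beta=1.5, gamma=0.7, K=2.0, n=4, c=1)
        assert ModelParams.from_json(p.to_json()) == p

    def test_json_round_trip_infinite_n(self):
        p = ModelParams(beta=1.5, gamma=0.7, K=2.0, n=INFINITE_N, c=2)
        encoded = p.to_json()
        assert '"inf"' in encoded
        assert ModelParams.from_json(encoded) == p

    def test_infinite_K_encodes_no_repression(self):
        p = ModelParams(beta=1, gamma=1, K=math.inf, n=INFINITE_N, c=2)
        assert ModelParams.from_json(p.to_json()) == p


class TestHillProduction:
    def test_zero_repressor_gives_full_production(self):
        p = ModelParams(beta=2.0, gamma=1.0, K=0.8, n=6, c=2)
        assert fm.hill_production(0.0, p) == pytest.approx(p.c * p.beta)

    def test_half_maximal_at_threshold(self):
        p = ModelParams(beta=1.0, gamma=1.0, K=0.3, n=4, c=1)
        assert fm.hill_production(p.K, p) == pytest.approx(0.5)

    def test_worked_value(self):
        # 2*1*0.5^4 / (1^4 + 0.5^4) = 2/17
        p = ModelParams(beta=1.0, gamma=1.0, K=0.5, n=4, c=2)
        assert fm.hill_production(1.0, p) == pytest.approx(2.0 / 17.0, rel=1e-12)

    def test_negative_level_rejected(self):
        p = ModelParams(beta=1, gamma=1, K=1, n=4, c=1)
        with pytest.raises(ValueError):
            fm.hill_production(-0.1, p)

    def test_infinite_n_rejected(self):
        p = ModelParams(beta=1, gamma=1, K=1, n=INFINITE_N, c=1)
        with pytest.raises(ValueError):
            fm.hill_production(0.5, p)

    def test_algebraic_forms_agree_on_random_grid(self, rng):
        # c*beta*K^n/(m^n + K^n) == c*beta/(1 + (m/K)^n), 10^4 draws
        for _ in range(10_000):
            m = rng.uniform(0, 5)
            p = ModelParams(
                beta=rng.uniform(0.1, 5),
                gamma=1.0,
                K=rng.uniform(0.1, 5),
                n=rng.uniform(0.5, 20),
                c=int(rng.integers(1, 3)),
            )
            form1 = p.c * p.beta * p.K**p.n / (m**p.n + p.K**p.n)
            assert fm.hill_production(m, p) == pytest.approx(form1, rel=1e-12)


class TestSteadyStateHill:
    def test_exact_algebraic_root(self):
        # 16*0.5^5 + 0.5 = 1 = c*beta/gamma, so m = 0.5 solves it exactly
        p = ModelParams(beta=1, gamma=1, K=0.5, n=4, c=1)
        assert fm.steady_state_hill(p).m_ss == pytest.approx(0.5, abs=1e-10)

    def test_two_copy_value_against_bisection_oracle(self, hill_params):
        # root of 16 m^5 + m - 2 = 0
        expected = bisect_steady_state(hill_params)
        assert expected == pytest.approx(0.613169676, abs=1e-8)
        assert fm.steady_state_hill(hill_params).m_ss == pytest.approx(
            expected, abs=1e-10
        )

    def test_huge_K_gives_unrepressed_level(self):
        p = ModelParams(beta=1.3, gamma=0.5, K=1e12, n=4, c=2)
        ss = fm.steady_state_hill(p)
        assert ss.m_ss == pytest.approx(p.c * p.beta / p.gamma, rel=1e-6)
        assert ss.regime == "unrepressed"

    @settings(max_examples=100, deadline=None)
    @given(finite_params)
    def test_residual_vanishes_at_root(self, p):
        m = fm.steady_state_hill(p).m_ss
        assert fm.hill_production(m, p) == pytest.approx(p.gamma * m, abs=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(finite_params)
    def test_monotone_in_beta_gamma_and_copies(self, p):
        base = fm.steady_state_hill(p).m_ss
        more_beta = fm.steady_state_hill(
            ModelParams(p.beta * 1.5, p.gamma, p.K, p.n, p.c)
        ).m_ss
        more_gamma = fm.steady_state_hill(
            ModelParams(p.beta, p.gamma * 1.5, p.K, p.n, p.c)
        ).m_ss
        assert more_beta >= base - 1e-12
        assert more_gamma <= base + 1e-12
        m1 = fm.steady_state_hill(p.with_copies(1)).m_ss
        m2 = fm.steady_state_hill(p.with_copies(2)).m_ss
        assert m2 >= m1 - 1e-12

    def test_converges_monotonically_to_step_limit(self):
        p_step = ModelParams(beta=0.6, gamma=1.0, K=1.0, n=INFINITE_N, c=2)
        target = fm.steady_state_step(p_step).m_ss
        gaps = [
            abs(
                fm.steady_state_hill(
                    ModelParams(0.6, 1.0, 1.0, n, 2)
                ).m_ss
                - target
            )
            for n in (4, 16, 64, 256)
        ]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.01


class TestSteadyStateStep:
    def test_repressed_pins_at_threshold(self):
        p = ModelParams(beta=1.2, gamma=1.0, K=1.0, n=INFINITE_N, c=2)
        ss = fm.steady_state_step(p)
        assert ss.m_ss == 1.0 and ss.regime == "repressed"

    def test_unrepressed_at_production_level(self):
        p = ModelParams(beta=0.73, gamma=1.0, K=1.0, n=INFINITE_N, c=1)
        ss = fm.steady_state_step(p)
        assert ss.m_ss == pytest.approx(0.73) and ss.regime == "unrepressed"

    def test_boundary_convention(self):
        # theta(0) = 1: m = K is the fixed point at equality
        p = ModelParams(beta=1.0, gamma=1.0, K=1.0, n=INFINITE_N, c=1)
        ss = fm.steady_state_step(p)
        assert ss.m_ss == 1.0 and ss.regime == "boundary"

    def test_finite_n_rejected(self):
        with pytest.raises(ValueError):
            fm.steady_state_step(ModelParams(1, 1, 1, 4, 1))


class TestIntegrateODE:
    def test_fixed_point_stays_constant(self, hill_params):
        m_ss = fm.steady_state_hill(hill_params).m_ss
        points = fm.integrate_ode(hill_params, m_ss, t_end=5.0, dt=0.01)
        assert all(pt.m == pytest.approx(m_ss, abs=1e-9) for pt in points)

    def test_converges_from_zero(self, hill_params):
        points = fm.integrate_ode(hill_params, 0.0, t_end=40.0, dt=0.01)
        assert points[-1].m == pytest.approx(0.613169676, abs=1e-6)

    def test_no_repression_reaches_linear_steady_state(self):
        p = ModelParams(beta=2.0, gamma=1.0, K=1e9, n=4, c=1)
        points = fm.integrate_ode(p, 0.0, t_end=40.0, dt=0.01)
        assert points[-1].m == pytest.approx(2.0, rel=1e-6)

    def test_monotone_convergence_from_either_side(self, hill_params):
        m_ss = fm.steady_state_hill(hill_params).m_ss
        for m0 in (0.0, 2.0):
            levels = [pt.m for pt in fm.integrate_ode(hill_params, m0, 30.0, 0.01)]
            diffs = np.diff(levels)
            assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)
            assert levels[-1] == pytest.approx(m_ss, abs=1e-6)

    def test_terminal_agreement_on_random_parameters(self, rng):
        for _ in range(20):
            p = ModelParams(
                beta=rng.uniform(0.2, 3),
                gamma=rng.uniform(0.5, 2),
                K=rng.uniform(0.2, 3),
                n=rng.uniform(1, 8),
                c=int(rng.integers(1, 3)),
            )
            expected = fm.steady_state_hill(p).m_ss
            points = fm.integrate_ode(p, 0.0, t_end=60.0 / p.gamma, dt=0.005)
            assert points[-1].m == pytest.approx(expected, abs=1e-6)

    def test_invalid_steps_rejected(self, hill_params):
        with pytest.raises(ValueError):
            fm.integrate_ode(hill_params, 0.0, t_end=1.0, dt=0.0)


class TestDosageRatio:
    def test_no_repression_is_exactly_half(self):
        p = ModelParams(beta=1.7, gamma=0.9, K=math.inf, n=INFINITE_N, c=2)
        assert fm.dosage_ratio_model(p) == 0.5

    def test_step_deep_repression_is_one(self):
        p = ModelParams(beta=1.2, gamma=1.0, K=1.0, n=INFINITE_N, c=2)
        assert fm.dosage_ratio_model(p) == 1.0

    def test_hill_reference_value(self, hill_params):
        m1 = bisect_steady_state(hill_params.with_copies(1))
        m2 = bisect_steady_state(hill_params.with_copies(2))
        assert fm.dosage_ratio_model(hill_params) == pytest.approx(
            m1 / m2, abs=1e-9
        )
        assert fm.dosage_ratio_model(hill_params) == pytest.approx(0.8154, abs=1e-4)

    @settings(max_examples=200, deadline=None)
    @given(finite_params)
    def test_ratio_bounded(self, p):
        rho = fm.dosage_ratio_model(p)
        assert 0.5 - 1e-9 <= rho <= 1.0 + 1e-9


class TestSolveHillThreshold:
    def test_round_trip_reference(self, hill_params):
        rho = fm.dosage_ratio_model(hill_params)
        m2 = fm.steady_state_hill(hill_params).m_ss
        sol = fm.solve_hill_threshold(rho, m2, n=4)
        assert sol.valid
        assert sol.K == pytest.approx(0.5, rel=1e-8)
        assert sol.beta_over_gamma == pytest.approx(1.0, rel=1e-8)

    def test_inadmissible_returns_invalid_not_exception(self):
        # 2 * 0.98^21 > 1, denominator negative
        assert 2 * 0.98**21 > 1
        sol = fm.solve_hill_threshold(0.98, 1.0, n=20)
        assert not sol.valid
        assert math.isnan(sol.K)

    def test_near_half_ratio_threshold_far_above_levels(self):
        sol = fm.solve_hill_threshold(0.501, 1.0, n=4)
        assert sol.valid
        assert sol.K > 3.0  # repression barely engaged

    @pytest.mark.parametrize("rho", [0.4, 0.5, 1.0, 1.2])
    def test_domain_errors(self, rho):
        with pytest.raises(ValueError):
            fm.solve_hill_threshold(rho, 1.0, n=4)

    def test_json_round_trip(self):
        sol = fm.solve_hill_threshold(0.8, 1.0, n=4)
        assert HillSolution.from_json(sol.to_json()) == sol

    @settings(max_examples=200, deadline=None)
    @given(
        K=st.floats(0.2, 3.0),
        bg=st.floats(0.1, 5.0),
        n=st.floats(1.0, 30.0),
    )
    def test_inversion_round_trip_random_grid(self, K, bg, n):
        p = ModelParams(beta=bg, gamma=1.0, K=K, n=n, c=2)
        m2 = fm.steady_state_hill(p).m_ss
        m1 = fm.steady_state_hill(p.with_copies(1)).m_ss
        rho = m1 / m2
        if not 0.5 + 1e-6 < rho < 1.0 - 1e-9:
            return  # outside the invertible range
        sol = fm.solve_hill_threshold(rho, m2, n)
        assert sol.valid
        assert sol.K == pytest.approx(K, rel=1e-6, abs=1e-6)
        assert sol.beta_over_gamma == pytest.approx(bg, rel=1e-6, abs=1e-6)


class TestMinHillCoefficient:
    def test_closed_form_value(self):
        assert fm.min_hill_coefficient(0.75) == pytest.approx(
            math.log(0.5) / math.log(0.75) - 1, rel=1e-12
        )
        assert fm.min_hill_coefficient(0.75) == pytest.approx(1.4094, abs=1e-4)

    def test_control_ratio_bound_exceeds_thirty(self):
        assert fm.min_hill_coefficient(0.98) >= 30
        assert fm.min_hill_coefficient(0.98) == pytest.approx(33.31, abs=0.01)

    def test_limit_toward_half_is_zero(self):
        assert fm.min_hill_coefficient(0.5 + 1e-12) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("rho", [0.5, 1.0, 0.2])
    def test_domain_errors(self, rho):
        with pytest.raises(ValueError):
            fm.min_hill_coefficient(rho)

    @pytest.mark.parametrize("rho", np.linspace(0.55, 0.97, 9).tolist())
    def test_validity_flips_exactly_at_bound(self, rho):
        # oracle: scan solver validity on an n grid around n_min
        n_min = fm.min_hill_coefficient(rho)
        for n in np.linspace(max(n_min - 2, 0.05), n_min + 2, 41):
            if abs(n - n_min) < 1e-9 or n <= 0:
                continue
            sol = fm.solve_hill_threshold(rho, 1.0, float(n))
            assert sol.valid == (n > n_min)


class TestSolveMutantHill:
    def test_identity_case_recovers_control(self, hill_params):
        rho = fm.dosage_ratio_model(hill_params)
        m2 = fm.steady_state_hill(hill_params).m_ss
        control = fm.solve_hill_threshold(rho, m2, n=4)
        n_mut, K_mut = fm.solve_mutant_hill(control, rho * m2, m2)
        assert n_mut == pytest.approx(4.0, rel=1e-6)
        assert K_mut == pytest.approx(0.5, rel=1e-6)

    def test_synthetic_mutant_recovery(self, hill_params):
        rho_c = fm.dosage_ratio_model(hill_params)
        m2_c = fm.steady_state_hill(hill_params).m_ss
        control = fm.solve_hill_threshold(rho_c, m2_c, n=4)
        # mutant with the same beta/gamma but (K', n') = (0.7, 6)
        mut = ModelParams(beta=1.0, gamma=1.0, K=0.7, n=6, c=2)
        m2_m = fm.steady_state_hill(mut).m_ss
        m1_m = fm.steady_state_hill(mut.with_copies(1)).m_ss
        n_mut, K_mut = fm.solve_mutant_hill(control, m1_m, m2_m)
        assert n_mut == pytest.approx(6.0, rel=0.01)
        assert K_mut == pytest.approx(0.7, rel=0.01)
        # forward solve reproduces the mutant levels
        recovered = ModelParams(beta=1.0, gamma=1.0, K=K_mut, n=n_mut, c=2)
        assert fm.steady_state_hill(recovered).m_ss == pytest.approx(m2_m, abs=1e-6)
        assert fm.steady_state_hill(recovered.with_copies(1)).m_ss == pytest.approx(
            m1_m, abs=1e-6
        )

    def test_near_null_mutant_yields_weak_cooperativity(self, hill_params):
        # a ratio of 0.52 is barely above the no-feedback value, so the
        # shared-production solution exists only with very low n
        rho_c = fm.dosage_ratio_model(hill_params)
        m2_c = fm.steady_state_hill(hill_params).m_ss
        control = fm.solve_hill_threshold(rho_c, m2_c, n=4)
        n_mut, K_mut = fm.solve_mutant_hill(control, 1.42 * 0.52, 1.42)
        assert n_mut < 2.0
        assert K_mut > m2_c  # repression barely engaged

    def test_no_admissible_solution_flagged(self, hill_params):
        rho_c = fm.dosage_ratio_model(hill_params)
        m2_c = fm.steady_state_hill(hill_params).m_ss
        control = fm.solve_hill_threshold(rho_c, m2_c, n=4)
        # mutant 1-copy level above the shared beta/gamma: impossible
        with pytest.raises(NoAdmissibleSolution):
            fm.solve_mutant_hill(control, mutant_m1=1.3, mutant_m2=2.0)

    def test_ratio_at_or_below_half_flagged(self, hill_params):
        rho_c = fm.dosage_ratio_model(hill_params)
        m2_c = fm.steady_state_hill(hill_params).m_ss
        control = fm.solve_hill_threshold(rho_c, m2_c, n=4)
        with pytest.raises(NoAdmissibleSolution):
            fm.solve_mutant_hill(control, mutant_m1=0.5, mutant_m2=1.0)


class TestCategorize:
    @pytest.mark.parametrize(
        "rho,expected", [(0.98, 1), (0.75, 2), (0.52, 3), (0.9, 1), (0.6, 3)]
    )
    def test_assignments(self, rho, expected):
        assert fm.categorize(rho) == expected

    def test_overshoot_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert fm.categorize(1.05) == 1

    @pytest.mark.parametrize("rho", [0.0, -0.3, 1.2])
    def test_domain_errors(self, rho):
        with pytest.raises(ValueError):
            fm.categorize(rho)

    def test_configurable_thresholds(self):
        assert fm.categorize(0.85, cat1_threshold=0.8) == 1
        assert fm.categorize(0.65, cat3_threshold=0.7) == 3


class TestInferStepParams:
    def test_category1_threshold_point_production_bound(self):
        res = fm.infer_step_params(1, 1.0, 1.0)
        assert res.K_est == 1.0 and not res.K_is_bound
        assert res.bg_est == 1.0 and res.bg_is_bound

    def test_category2_both_points(self):
        res = fm.infer_step_params(2, 0.73, 1.0)
        assert res.K_est == 1.0 and not res.K_is_bound
        assert res.bg_est == 0.73 and not res.bg_is_bound

    def test_category3_production_point_threshold_bound(self):
        res = fm.infer_step_params(3, 0.71, 1.42)
        assert res.bg_est == 0.71 and not res.bg_is_bound
        assert res.K_est == 1.42 and res.K_is_bound

    def test_category3_inconsistency_warns(self):
        with pytest.warns(UserWarning, match="inconsistency"):
            fm.infer_step_params(3, 0.71, 2.5)

    def test_json_round_trip(self):
        res = fm.infer_step_params(2, 0.73, 1.0)
        assert CategoryResult.from_json(res.to_json()) == res


class TestNoFeedback:
    def test_linear_steady_state(self):
        assert fm.no_feedback_steady_state(1.0, 1.0, 2).m_ss == 2.0
        assert fm.no_feedback_steady_state(0.0, 1.0, 1).m_ss == 0.0

    @settings(max_examples=100, deadline=None)
    @given(beta=st.floats(0.01, 100.0), gamma=st.floats(0.01, 100.0))
    def test_ratio_always_half(self, beta, gamma):
        m1 = fm.no_feedback_steady_state(beta, gamma, 1).m_ss
        m2 = fm.no_feedback_steady_state(beta, gamma, 2).m_ss
        assert m1 / m2 == pytest.approx(0.5, rel=1e-12)


class TestDistanceEffect:
    @pytest.fixture
    def step_params(self):
        return ModelParams(beta=1.2, gamma=1.0, K=1.0, n=INFINITE_N, c=2)

    def test_beta_increase_alone_leaves_repressed_state(self, step_params):
        ss2, ss1, _ = fm.distance_effect_predict(step_params, 1.5, 1.0)
        assert ss2.m_ss == 1.0 and ss2.regime == "repressed"

    def test_K_increase_moves_repressed_state(self, step_params):
        ss2, _, _ = fm.distance_effect_predict(step_params, 1.0, 1.5)
        assert ss2.m_ss == 1.5  # 2*beta/gamma = 2.4 still exceeds 1.5

    def test_huge_beta_pins_both_copies(self, step_params):
        _, _, ratio = fm.distance_effect_predict(step_params, 100.0, 1.0)
        assert ratio == 1.0

    def test_combined_scaling(self, step_params):
        # K tripled beyond 2*beta/gamma: repression disengages entirely
        ss2, ss1, ratio = fm.distance_effect_predict(step_params, 1.0, 3.0)
        assert ss2.regime == "unrepressed" and ratio == 0.5


class TestHillVsStepError:
    def test_reference_comparison(self):
        report = fm.hill_vs_step_error(0.75, 1.0, 4)
        assert report.valid
        assert report.K_step == 1.0
        assert report.bg_step == 0.75
        hill = fm.solve_hill_threshold(0.75, 1.0, 4)
        assert report.K_rel_error == pytest.approx(abs(hill.K - 1.0), rel=1e-12)
        assert report.bg_rel_error == pytest.approx(
            abs(hill.beta_over_gamma - 0.75) / 0.75, rel=1e-12
        )

    def test_errors_vanish_at_large_n(self):
        errors = [fm.hill_vs_step_error(0.75, 1.0, n) for n in (8, 32, 128, 512)]
        k_errs = [e.K_rel_error for e in errors]
        bg_errs = [e.bg_rel_error for e in errors]
        assert all(a > b for a, b in zip(k_errs, k_errs[1:]))
        # bg error underflows to exactly 0 once rho^n vanishes in floats
        assert all(a >= b for a, b in zip(bg_errs, bg_errs[1:]))
        assert k_errs[-1] < 2e-3 and bg_errs[-1] < 1e-6

    def test_invalid_propagates(self):
        report = fm.hill_vs_step_error(0.98, 1.0, 4)
        assert not report.valid
        assert math.isnan(report.K_rel_error)
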