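import math

import numpy as np
import pytest

from ctrlbranch import (
    EnvironmentLaw,
    EnvironmentState,
    IdentityKernel,
    ensemble_normalized,
    get_scenario,
    l2_bound,
    mean_identity_check,
    nondegeneracy_condition,
    normalized_path,
    normalizers,
    propagate_distribution,
    r_statistic,
    series_conditions,
    simulate_ensemble,
    simulate_path,
    submartingale_step_check,
    supermartingale_step_check,
)
from ctrlbranch.limits import (
    doob_decomposition,
    growth_rate_regression,
    r_nonincreasing,
    surviving_path_condition,
)


class TestNormalizers:
    def test_critical_identity_all_ones(self, theta1, single_state_law):
        norm = normalizers(single_state_law(theta1), np.zeros(10, dtype=int), 1)
        np.testing.assert_allclose(norm.log_S, 0.0, atol=1e-12)
        np.testing.assert_allclose(norm.log_I, 0.0, atol=1e-12)

    def test_emigration_splits_sup_inf(self, theta1_em, single_state_law):
        # m*alpha = 1: S_n = 1, I_n = 0.5^n
        norm = normalizers(single_state_law(theta1_em), np.zeros(6, dtype=int), 1)
        np.testing.assert_allclose(norm.log_S, 0.0, atol=1e-12)
        np.testing.assert_allclose(norm.log_I, np.arange(7) * math.log(0.5), atol=1e-12)

    def test_zero_length(self, theta1, single_state_law):
        norm = normalizers(single_state_law(theta1), np.zeros(0, dtype=int), 3)
        assert norm.log_S[0] == norm.log_I[0] == pytest.approx(math.log(3))

    def test_eps1_zero_raises(self, single_state_law):
        from ctrlbranch import EmigrationKernel

        state = EnvironmentState("allout", np.array([0.25, 0.25, 0.5]), 0.8, EmigrationKernel([0.0, 1.0]))
        with pytest.raises(ValueError, match="W_bar"):
            normalizers(single_state_law(state), np.zeros(3, dtype=int), 1)


class TestNormalizedPaths:
    def test_identity_critical_w_hat_is_z(self, theta1, single_state_law):
        traj = simulate_path(single_state_law(theta1), 1, 20, 3)
        path = normalized_path(traj, single_state_law(theta1))
        np.testing.assert_allclose(path.W_hat, traj.Z.astype(float), atol=1e-12)

    def test_w_bar_dominates_w_hat_and_zero_after_extinction(self, theta1_em, single_state_law):
        law = single_state_law(theta1_em)
        for seed in range(10):
            traj = simulate_path(law, 2, 30, seed)
            path = normalized_path(traj, law)
            assert np.all(path.W_bar >= path.W_hat - 1e-12)
            if traj.extinct_at is not None:
                assert np.all(path.W_hat[traj.extinct_at :] == 0.0)
                assert np.all(path.W_bar[traj.extinct_at :] == 0.0)


class TestMartingaleRatios:
    def test_identity_is_martingale(self, theta1):
        for i in (1, 2, 5, 10):
            assert supermartingale_step_check(theta1, i) == pytest.approx(1.0)
            assert submartingale_step_check(theta1, i) == pytest.approx(1.0)

    def test_emigration_ratios(self, theta1_em):
        assert supermartingale_step_check(theta1_em, 1) == pytest.approx(0.5)
        assert supermartingale_step_check(theta1_em, 10) == pytest.approx(0.95)
        assert submartingale_step_check(theta1_em, 1) == pytest.approx(1.0)
        assert submartingale_step_check(theta1_em, 4) == pytest.approx(0.875 / 0.5)

    def test_super_at_most_one_sub_at_least_one(self, scenario):
        for state in scenario.law.states:
            for i in range(1, 31):
                assert supermartingale_step_check(state, i) <= 1 + 1e-12
                assert submartingale_step_check(state, i) >= 1 - 1e-12


class TestMeanIdentity:
    def test_identity_control_exact_via_propagation(self, theta1, single_state_law):
        # with identity control E(W_hat_n) = 1 exactly: check via exact propagation
        law = single_state_law(theta1)
        dists = propagate_distribution([theta1] * 10, 1, j_max=1024)
        for d in dists:
            assert d.mean() == pytest.approx(1.0, abs=1e-9 + 1024 * d.tail_mass)

    def test_monte_carlo_identity_holds(self):
        sc = get_scenario("S5_emigration")
        rep = mean_identity_check(sc.law, sc.n0, 10, 4000, 123)
        assert rep.passed, f"deviation {rep.deviation_sigmas:.2f} sigma"

    def test_doob_compensated_martingale(self):
        sc = get_scenario("S5_emigration")
        ens = simulate_ensemble(sc.law, sc.n0, 15, 4000, 7, cap=10**12)
        w_hat, T = doob_decomposition(ens, sc.law)
        y = w_hat + T  # martingale: mean constant = 1
        for t in (5, 10, 15):
            se = y[:, t].std(ddof=1) / math.sqrt(ens.reps)
            assert abs(y[:, t].mean() - 1.0) < 4 * se


class TestL2Bound:
    def test_supercritical_geometric_series(self, theta3, single_state_law):
        rep = l2_bound(single_state_law(theta3), 1, None)
        # 1 + (2.6/1.568) * 1.12/0.12, no control-variance term
        assert rep.bound == pytest.approx(16.47619047619, abs=1e-9)
        assert rep.verdict == "converged-to-finite"

    def test_identity_no_control_term(self, theta3, single_state_law):
        # finite-n partial bound only carries the offspring series
        rep = l2_bound(single_state_law(theta3), 1, 5)
        a1 = 2.6 / (0.8 * 1.4**2)
        expect = 1.0 + a1 * np.sum(1.12 ** -np.arange(6.0))
        assert rep.partial[-1] == pytest.approx(expect, abs=1e-12)

    def test_subcritical_diverges(self, single_state_law):
        law = get_scenario("S2_subcritical").law
        rep = l2_bound(law, 1, None)
        assert rep.verdict == "diverging"

    def test_binomial_thinning_inapplicable(self):
        from ctrlbranch import BinomialThinningKernel

        state = EnvironmentState("b", np.array([0.2, 0.2, 0.6]), 0.8, BinomialThinningKernel(0.9))
        rep = l2_bound(EnvironmentLaw([state], np.array([1.0])), 1, None)
        assert rep.verdict == "inapplicable"

    def test_bound_dominates_empirical_second_moment(self, theta3, single_state_law):
        law = single_state_law(theta3)
        ens = simulate_ensemble(law, 1, 15, 5000, 31, cap=10**12)
        w = ensemble_normalized(ens, law)
        w2 = w[:, 15] ** 2
        bound = l2_bound(law, 1, None).bound
        assert w2.mean() <= bound + 3 * w2.std(ddof=1) / math.sqrt(ens.reps)


class TestConditionSeries:
    def test_identity_control_series(self, theta3, single_state_law):
        reports = {c.theorem: c for c in series_conditions(single_state_law(theta3), 1)}
        assert reports["supermartingale_L2_offspring"].verdict == "converged-to-finite"
        assert reports["supermartingale_L2_control"].verdict == "converged-to-finite"
        assert np.all(reports["supermartingale_L2_control"].terms == 0.0)
        assert reports["L2_convergence_spread"].verdict == "converged-to-finite"
        assert reports["submartingale_mean_bound"].verdict == "converged-to-finite"
        np.testing.assert_allclose(reports["submartingale_mean_bound"].partial, 1.0)

    def test_emigration_submartingale_diverges(self, theta1_em, single_state_law):
        reports = {c.theorem: c for c in series_conditions(single_state_law(theta1_em), 1)}
        # E[eps/eps1] = 2 per step: partial products 2^n
        assert reports["submartingale_mean_bound"].verdict == "diverging"
        assert reports["L2_convergence_spread"].verdict == "diverging"


class TestNondegeneracy:
    def test_identity_product_one(self, theta3, single_state_law):
        rep = nondegeneracy_condition(single_state_law(theta3), 1)
        assert rep.verdict == "nondegenerate"
        np.testing.assert_allclose(rep.partial, 1.0)

    def test_emigration_supercritical_positive(self):
        sc = get_scenario("S5_emigration")
        rep = nondegeneracy_condition(sc.law, sc.n0)
        assert rep.verdict == "nondegenerate"
        assert rep.partial[-1] > 0.15

    def test_subcritical_inconclusive(self, theta1_em, single_state_law):
        # arguments decay to 0: factors stick at eps(1)/eps_sup = 0.5, product -> 0
        law = single_state_law(
            EnvironmentState("sub_em", np.array([0.25, 0.25, 0.5]), 0.72, theta1_em.control)
        )
        rep = nondegeneracy_condition(law, 1)
        assert rep.verdict == "inconclusive"

    def test_immigration_inapplicable(self):
        from ctrlbranch import ImmigrationKernel

        state = EnvironmentState("imm", np.array([0.2, 0.2, 0.6]), 0.8, ImmigrationKernel([0.5, 0.5]))
        rep = nondegeneracy_condition(EnvironmentLaw([state], np.array([1.0])), 1)
        assert rep.verdict == "theorem_inapplicable"


class TestRStatistic:
    def test_hand_values_critical(self, theta1):
        assert r_statistic(theta1, 1) == pytest.approx(0.8)
        assert r_statistic(theta1, 2) == pytest.approx(0.48)

    def test_degenerate_zero(self):
        state = EnvironmentState("deg", np.array([0.0, 1.0]), 1.0, IdentityKernel())
        for k in (1, 2, 8):
            assert r_statistic(state, k) == pytest.approx(0.0, abs=1e-12)

    def test_nonincreasing_probe(self, theta1):
        assert r_nonincreasing(theta1)

    def test_emigration_r_turns_upward(self):
        # with eps1 = 1/2 strictly below eps(k) -> 1, the normalized L1 step
        # deviation tends to m*alpha*(1 - eps1) = 1.2 > r_4, so the sequence
        # is not nonincreasing: it dips and then rises toward its limit
        st = get_scenario("S5_emigration").law.states[0]
        vals = [r_statistic(st, k) for k in (1, 2, 4, 8, 16, 32)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < vals[3] < vals[4] < vals[5] < 1.2
        assert not r_nonincreasing(st)


class TestSurvivingPath:
    def test_identity_all_zero(self, theta1, single_state_law):
        traj = simulate_path(single_state_law(theta1), 1, 20, 0)
        partial, _ = surviving_path_condition(traj, single_state_law(theta1))
        np.testing.assert_allclose(partial, 0.0)

    def test_emigration_terms_decay_on_survivors(self):
        sc = get_scenario("S5_emigration")
        for seed in range(30):
            traj = simulate_path(sc.law, sc.n0, 40, seed, cap=10**12)
            partial, truncated = surviving_path_condition(traj, sc.law)
            if traj.extinct_at is None:
                # terms 0.5/Z_k with Z growing geometrically: series flattens
                assert partial[-1] - partial[-10] < 0.01
                assert not truncated


class TestGrowthRecovery:
    def test_supercritical_log_slope(self, theta3, single_state_law):
        law = single_state_law(theta3)
        ens = simulate_ensemble(law, 1, 15, 10_000, 2)
        slope = growth_rate_regression(ens, 5, 15)
        assert slope == pytest.approx(math.log(1.12), abs=0.02)
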