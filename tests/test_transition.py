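import itertools

import numpy as np
import pytest

from ctrlbranch import (
    SizedPmf,
    conditional_mean,
    conditional_variance,
    convolve_power,
    one_step_pmf,
    propagate_distribution,
    sample_environment_sequence,
    thinned_offspring_pmf,
)


def brute_force_one_step(state, i, j_max=64):
    """Independent oracle: enumerate all (offspring, indicator) tuples.

    For each participation count k, sums the probability of every tuple
    ((r_1, d_1), ..., (r_k, d_k)) with sum r_l d_l = j, each factor carrying
    probability P_{r_l} * alpha^{d_l} (1-alpha)^{1-d_l}.  Exponential in k;
    usable only for tiny instances.
    """
    out = np.zeros(j_max + 1)
    q = state.control.pmf(i)
    pr = state.offspring_pmf
    singles = [
        (r * d, pr[r] * (state.alpha if d else 1 - state.alpha))
        for r in range(pr.size)
        for d in (0, 1)
    ]
    for k, qk in enumerate(q):
        if qk == 0:
            continue
        for combo in itertools.product(singles, repeat=k):
            j = sum(c[0] for c in combo)
            p = qk
            for c in combo:
                p *= c[1]
            out[j] += p
    return out


class TestThinnedOffspring:
    def test_theta1(self, theta1):
        p = thinned_offspring_pmf(theta1)
        np.testing.assert_allclose(p.probs, [0.4, 0.2, 0.4])
        assert p.tail_mass == 0.0

    def test_alpha_one_unchanged(self, theta1):
        import dataclasses

        st = dataclasses.replace(theta1, alpha=1.0)
        np.testing.assert_allclose(thinned_offspring_pmf(st).probs, st.offspring_pmf)

    def test_tiny_alpha_concentrates_at_zero(self, theta1):
        import dataclasses

        st = dataclasses.replace(theta1, alpha=1e-12)
        p = thinned_offspring_pmf(st)
        assert p.probs[0] == pytest.approx(1.0, abs=1e-11)


class TestConvolvePower:
    def test_hand_convolution(self):
        base = SizedPmf(np.array([0.4, 0.2, 0.4]))
        p2 = convolve_power(base, 2)
        np.testing.assert_allclose(p2.probs[:5], [0.16, 0.16, 0.36, 0.16, 0.16], atol=1e-15)

    def test_k_zero_and_one(self):
        base = SizedPmf(np.array([0.4, 0.2, 0.4]))
        np.testing.assert_allclose(convolve_power(base, 0).probs, [1.0])
        np.testing.assert_allclose(convolve_power(base, 1).probs, base.probs)

    def test_truncation_tracks_tail(self):
        base = SizedPmf(np.array([0.5, 0.5]))
        p = convolve_power(base, 10, j_max=3)
        assert p.tail_mass > 0
        assert p.probs.sum() + p.tail_mass == pytest.approx(1.0, abs=1e-12)

    def test_matches_binomial(self):
        # 8-fold convolution of a Bernoulli(0.3) is Binomial(8, 0.3)
        from scipy.stats import binom

        p = convolve_power(SizedPmf(np.array([0.7, 0.3])), 8)
        np.testing.assert_allclose(p.probs, binom.pmf(np.arange(9), 8, 0.3), atol=1e-14)


class TestOneStep:
    def test_identity_examples(self, theta1):
        np.testing.assert_allclose(one_step_pmf(theta1, 1).trimmed().probs, [0.4, 0.2, 0.4], atol=1e-15)
        np.testing.assert_allclose(
            one_step_pmf(theta1, 2).trimmed().probs, [0.16, 0.16, 0.36, 0.16, 0.16], atol=1e-15
        )

    def test_absorbing_zero(self, theta1):
        p = one_step_pmf(theta1, 0)
        np.testing.assert_allclose(p.probs, [1.0])

    def test_emigration_mixture(self, theta1_em):
        # phi(1) is 0 or 1 with prob 1/2: mixture 0.5*delta_0 + 0.5*thinned pmf
        p = one_step_pmf(theta1_em, 1).trimmed()
        np.testing.assert_allclose(p.probs, [0.7, 0.1, 0.2], atol=1e-15)

    @pytest.mark.parametrize("i", [1, 2, 3, 4])
    def test_brute_force_oracle(self, theta1, theta1_em, theta3, i):
        for state in (theta1, theta1_em, theta3):
            exact = one_step_pmf(state, i, j_max=64)
            oracle = brute_force_one_step(state, i)
            np.testing.assert_allclose(exact.probs, oracle[: exact.probs.size], atol=1e-12)


class TestConditionalMoments:
    def test_hand_values(self, theta1, theta1_em):
        assert conditional_mean(theta1, 1) == pytest.approx(1.0)
        assert conditional_mean(theta1, 2) == pytest.approx(2.0)
        assert conditional_mean(theta1, 0) == 0.0
        assert conditional_mean(theta1_em, 1) == pytest.approx(0.5)
        assert conditional_variance(theta1, 1) == pytest.approx(0.8)
        assert conditional_variance(theta1, 2) == pytest.approx(1.6)
        # direct moments of {0:0.7, 1:0.1, 2:0.2}: mean 0.5, var 0.65
        assert conditional_variance(theta1_em, 1) == pytest.approx(0.65)

    def test_match_exact_pmf_moments(self, scenario):
        for state in scenario.law.states:
            for i in range(31):
                pmf = one_step_pmf(state, i, j_max=8192)
                tol = 1e-9 + 8192 * pmf.tail_mass
                assert pmf.mean() == pytest.approx(conditional_mean(state, i), abs=tol)
                assert pmf.var() == pytest.approx(conditional_variance(state, i), abs=max(tol, 1e-8))


class TestPropagate:
    def test_single_step(self, theta1):
        dists = propagate_distribution([theta1], 1)
        np.testing.assert_allclose(dists[1].trimmed().probs, [0.4, 0.2, 0.4], atol=1e-15)

    def test_critical_mean_constant(self, theta1):
        dists = propagate_distribution([theta1] * 10, 1, j_max=1024)
        for d in dists:
            assert d.mean() == pytest.approx(1.0, abs=1e-9 + 1024 * d.tail_mass)

    def test_extinction_mass_nondecreasing(self, theta1):
        dists = propagate_distribution([theta1] * 10, 1, j_max=1024)
        p0 = [d.probs[0] for d in dists]
        assert np.all(np.diff(p0) >= -1e-15)

    def test_tail_mass_nondecreasing(self, theta3):
        dists = propagate_distribution([theta3] * 12, 4, j_max=64)
        tails = [d.tail_mass for d in dists]
        assert np.all(np.diff(tails) >= -1e-15)

    def test_quenched_mean_sandwich(self, scenario):
        # N0 prod(m a eps1) <= E(Z_n | xi) <= N0 prod(m a eps) for mixed sequences
        idx = sample_environment_sequence(scenario.law, 6, 13)
        seq = [scenario.law.states[i] for i in idx]
        dists = propagate_distribution(seq, scenario.n0, j_max=4096)
        lo = hi = float(scenario.n0)
        for t, state in enumerate(seq, start=1):
            lo *= state.m * state.alpha * state.control.eps_inf
            hi *= state.m * state.alpha * state.control.eps_sup
            d = dists[t]
            slack = 1e-9 + 4096 * d.tail_mass
            assert lo - slack <= d.mean() <= hi + slack
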