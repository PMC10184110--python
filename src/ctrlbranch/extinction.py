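"""Extinction analysis via probability generating functions.

Three complementary tools:

* an annealed certain-extinction criterion: if the environment expectation
  of ``log(eta * N0 * alpha * m)`` is <= 0 (and a monotonicity hypothesis on
  the thinned pgf holds), the process dies out almost surely;
* a lower-bound iteration ``mu_n`` for the quenched extinction probability,
  built by backward composition of thinned pgfs raised to the dominating
  exponents;
* a Monte-Carlo finite-horizon extinction frequency with a Wilson score
  interval (an under-estimate of the true extinction probability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .environment import EnvironmentLaw, EnvironmentState, thinned_pgf
from .simulate import simulate_ensemble

__all__ = [
    "ExtinctionCriterionReport",
    "MuIteration",
    "extinction_criterion",
    "check_monotonicity_condition",
    "iterate_mu",
    "mc_extinction_probability",
]


@dataclass
class ExtinctionCriterionReport:
    """Annealed certain-extinction criterion and its hypothesis checks."""

    per_state_term: dict[str, float]  # log(eta * N0 * alpha * m) per state
    expectation: float
    monotonicity_ok: dict[str, bool]
    conclusion: str  # certain_extinction | criterion_positive | theorem_inapplicable
    reason: str = ""
    n0_sign_sensitive: bool = False  # criterion sign flips between N0=1 and the given N0


@dataclass
class MuIteration:
    """Lower-bound iterates mu_1..mu_n for the quenched extinction probability."""

    mu: np.ndarray
    converged: bool
    limit_estimate: float
    n0: int
    eta: np.ndarray  # per-step dominating exponents used


def _criterion_terms(law: EnvironmentLaw, n0: int) -> dict[str, float]:
    out = {}
    for st in law.states:
        if not math.isfinite(st.eta):
            out[st.label] = math.inf
        else:
            out[st.label] = math.log(st.eta * n0 * st.alpha * st.m)
    return out


def check_monotonicity_condition(
    state: EnvironmentState, n0: int, grid_size: int = 10_000, slope_tol: float = 1e-12
):
    """Numerically certify that g(s) = (1 - thinned_pgf(s)^(eta*N0)) / (1-s) increases on (0,1).

    The limit at s -> 1 is eta * N0 * alpha * m (appended as the final grid
    value).  Returns (ok, min_slope); a finite grid check, not a symbolic proof.
    """
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    e = state.eta * n0
    s = np.linspace(0.0, 1.0, grid_size + 1)[:-1]
    g = (1.0 - thinned_pgf(state, s) ** e) / (1.0 - s)
    g = np.append(g, e * state.alpha * state.m)  # s -> 1 limit (L'Hopital)
    slopes = np.diff(g)
    return bool(np.all(slopes > slope_tol)), float(slopes.min())


def extinction_criterion(law: EnvironmentLaw, n0: int, grid_size: int = 10_000) -> ExtinctionCriterionReport:
    """Evaluate the annealed certain-extinction criterion E[log(eta N0 alpha m)] <= 0.

    The expectation is computed exactly over the finite environment law.
    An infinite dominator eta makes the criterion inapplicable.
    """
    if n0 < 1:
        raise ValueError("initial size must be >= 1")
    terms = _criterion_terms(law, n0)
    if any(not math.isfinite(v) for v in terms.values()):
        return ExtinctionCriterionReport(
            per_state_term=terms,
            expectation=math.inf,
            monotonicity_ok={},
            conclusion="theorem_inapplicable",
            reason="eta = +inf for some state; no deterministic dominator",
        )
    expectation = law.expectation([terms[s.label] for s in law.states])
    mono = {s.label: check_monotonicity_condition(s, n0, grid_size)[0] for s in law.states}
    exp_n0_1 = law.expectation([v - math.log(n0) for v in (terms[s.label] for s in law.states)])
    sign_sensitive = (expectation <= 0) != (exp_n0_1 <= 0)
    if expectation <= 0 and all(mono.values()):
        conclusion, reason = "certain_extinction", ""
    elif expectation <= 0:
        bad = [k for k, v in mono.items() if not v]
        conclusion, reason = "theorem_inapplicable", f"monotonicity hypothesis fails for state(s) {bad}"
    else:
        conclusion, reason = "criterion_positive", "criterion > 0; the theorem is silent"
    return ExtinctionCriterionReport(
        per_state_term=terms,
        expectation=float(expectation),
        monotonicity_ok=mono,
        conclusion=conclusion,
        reason=reason,
        n0_sign_sensitive=bool(sign_sensitive),
    )


def iterate_mu(
    env_sequence: list[EnvironmentState],
    n0: int,
    n: int,
    eta: np.ndarray | None = None,
    tol: float = 1e-12,
) -> MuIteration:
    """Backward-composed lower-bound iterates for the quenched extinction probability.

    mu_k nests the thinned pgfs of the first k environment states, innermost
    first, each raised to its dominating exponent eta_t (the outermost level
    additionally carries N0):

        mu_k = [h_0((h_1(... (h_{k-1}(0))^{eta_{k-1}} ...))^{eta_1})]^{eta_0 N0},

    with h_t(s) = 1 - alpha_t + alpha_t f_t(s).  The sequence is monotone
    nondecreasing in [0, 1] and its limit is a lower bound on the quenched
    extinction probability.  Real (non-integer) exponents are allowed.
    """
    if n0 < 1 or n < 1:
        raise ValueError("need n0 >= 1 and n >= 1")
    if n > len(env_sequence):
        raise ValueError("environment sequence shorter than requested iterations")
    states = env_sequence
    if eta is None:
        eta = np.array([s.eta for s in states[:n]], dtype=float)
    else:
        eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("mu iteration needs finite eta for every state in the sequence")

    constant = all(s is states[0] for s in states[:n]) and np.all(eta == eta[0])
    mu = []
    if constant:
        st, e = states[0], float(eta[0])
        # inner nest with exponent eta only; outer level applies eta*N0
        v = 0.0
        for _ in range(n):
            mu_k = thinned_pgf(st, v) ** (e * n0)
            mu.append(mu_k)
            if len(mu) > 1 and abs(mu[-1] - mu[-2]) < tol:
                break
            v = thinned_pgf(st, v) ** e
    else:
        prev = None
        for k in range(1, n + 1):
            v = 0.0
            for t in range(k - 1, 0, -1):
                v = thinned_pgf(states[t], v) ** eta[t]
            mu_k = thinned_pgf(states[0], v) ** (eta[0] * n0)
            mu.append(mu_k)
            if prev is not None and abs(mu_k - prev) < tol:
                break
            prev = mu_k
    mu = np.array(mu)
    converged = mu.size >= 2 and abs(mu[-1] - mu[-2]) < tol
    return MuIteration(mu=mu, converged=bool(converged), limit_estimate=float(mu[-1]), n0=n0, eta=eta)


@dataclass
class McExtinctionEstimate:
    frequency: float
    ci_low: float
    ci_high: float
    reps: int
    horizon: int
    seed: object


def mc_extinction_probability(
    law: EnvironmentLaw, n0: int, n_max: int, reps: int, seed, mode: str = "compound"
) -> McExtinctionEstimate:
    """Finite-horizon Monte-Carlo extinction frequency with a Wilson 95% interval.

    Under-estimates the true extinction probability (paths may die after the
    horizon).
    """
    if reps < 100:
        raise ValueError("need reps >= 100 for a meaningful interval")
    ens = simulate_ensemble(law, n0, n_max, reps, seed, mode=mode)
    k = int(ens.extinct_by(n_max).sum())
    ci = binomtest(k, reps).proportion_ci(confidence_level=0.95, method="wilson")
    return McExtinctionEstimate(
        frequency=k / reps, ci_low=float(ci.low), ci_high=float(ci.high), reps=reps, horizon=n_max, seed=seed
    )
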