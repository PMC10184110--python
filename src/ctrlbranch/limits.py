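"""Normalizers, martingale diagnostics, and limit-theorem condition evaluators.

The conditional mean of the process satisfies the sandwich

    N0 * prod m(xi_k) alpha(xi_k) eps1(xi_k)  <=  E(Z_n | xi)
        <=  N0 * prod m(xi_k) alpha(xi_k) eps(xi_k),

which motivates two normalizers: ``S_n`` (sup participation rate ``eps``)
and ``I_n`` (inf participation rate ``eps1``).  ``W_hat_n = Z_n / S_n`` is a
nonnegative supermartingale and ``W_bar_n = Z_n / I_n`` a submartingale.
This module computes the normalizers (in log space), the normalized paths,
exact one-step martingale ratios, the L2 bound for the supermartingale,
the mean identity coupling E(W_hat_n) to the accumulated participation
deficit, and numerical certificates for the sufficient-condition series of
the L1/L2-convergence and nondegeneracy theorems.

All series verdicts are finite numerical certificates (ratio test over the
last computed terms), not proofs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentLaw, EnvironmentState
from .simulate import EnsembleResult, Trajectory, simulate_ensemble
from .transition import one_step_pmf

__all__ = [
    "NormalizerPath",
    "NormalizedPath",
    "ConditionReport",
    "normalizers",
    "normalized_path",
    "ensemble_normalized",
    "supermartingale_step_check",
    "submartingale_step_check",
    "mean_identity_check",
    "doob_decomposition",
    "l2_bound",
    "series_conditions",
    "nondegeneracy_condition",
    "default_envelope",
    "r_statistic",
    "r_nonincreasing",
    "surviving_path_condition",
    "growth_rate_regression",
]

RATIO_CONVERGING = 0.999
RATIO_DIVERGING = 1.001


# ---------------------------------------------------------------------------
# normalizers and normalized paths


@dataclass
class NormalizerPath:
    """Log-scale normalizer paths S_n (sup rate) and I_n (inf rate)."""

    log_S: np.ndarray
    log_I: np.ndarray
    env_indices: np.ndarray


@dataclass
class NormalizedPath:
    W_hat: np.ndarray  # Z_n / S_n
    W_bar: np.ndarray  # Z_n / I_n


def _log_factors(law: EnvironmentLaw, which: str) -> np.ndarray:
    out = np.empty(len(law.states))
    for s_idx, st in enumerate(law.states):
        eps = st.control.eps_sup if which == "sup" else st.control.eps_inf
        if eps <= 0.0:
            raise ValueError(f"state {st.label}: eps1 = 0, normalizer I_n identically 0; W_bar undefined")
        out[s_idx] = math.log(st.m * st.alpha * eps)
    return out


def normalizers(law: EnvironmentLaw, env_indices: np.ndarray, n0: int) -> NormalizerPath:
    """S_n and I_n along an environment sequence, computed in log space."""
    env_indices = np.asarray(env_indices, dtype=np.int64)
    lf_sup = _log_factors(law, "sup")[env_indices]
    lf_inf = _log_factors(law, "inf")[env_indices]
    log_n0 = math.log(n0)
    log_S = np.concatenate([[log_n0], log_n0 + np.cumsum(lf_sup)])
    log_I = np.concatenate([[log_n0], log_n0 + np.cumsum(lf_inf)])
    return NormalizerPath(log_S=log_S, log_I=log_I, env_indices=env_indices)


def normalized_path(trajectory: Trajectory, law: EnvironmentLaw, n0: int | None = None) -> NormalizedPath:
    """W_hat_n and W_bar_n for one trajectory; exact zeros after extinction."""
    if n0 is None:
        n0 = int(trajectory.Z[0])
    norm = normalizers(law, trajectory.env_indices, n0)
    z = trajectory.Z.astype(float)
    with np.errstate(divide="ignore"):
        logz = np.where(z > 0, np.log(np.maximum(z, 1.0)), -np.inf)
    w_hat = np.where(z > 0, np.exp(logz - norm.log_S), 0.0)
    w_bar = np.where(z > 0, np.exp(logz - norm.log_I), 0.0)
    return NormalizedPath(W_hat=w_hat, W_bar=w_bar)


def ensemble_normalized(ens: EnsembleResult, law: EnvironmentLaw, which: str = "sup") -> np.ndarray:
    """Matrix of normalized paths (reps x n+1) for a whole ensemble."""
    lf = _log_factors(law, which)[ens.env_indices]  # (reps, n)
    log_norm = np.concatenate(
        [np.full((ens.reps, 1), math.log(ens.n0)), math.log(ens.n0) + np.cumsum(lf, axis=1)], axis=1
    )
    z = ens.Z.astype(float)
    with np.errstate(divide="ignore"):
        logz = np.where(z > 0, np.log(np.maximum(z, 1.0)), -np.inf)
    return np.where(z > 0, np.exp(logz - log_norm), 0.0)


# ---------------------------------------------------------------------------
# one-step martingale ratios


def _eps_vec(state: EnvironmentState, k: np.ndarray) -> np.ndarray:
    """Vectorized participation rate eps(theta, k); defined 0 at k = 0."""
    k = np.asarray(k, dtype=np.int64)
    out = np.zeros(k.shape, dtype=float)
    for kv in np.unique(k):
        if kv >= 1:
            out[k == kv] = state.control.eps(int(kv))
    return out


def supermartingale_step_check(state: EnvironmentState, i: int, j_max: int = 4096, verify_tol: float = 1e-9) -> float:
    """One-step supermartingale ratio E(W_hat_{n+1}|F_n)/W_hat_n = eps(theta,i)/eps_sup.

    Independently verified against the mean of the exact one-step pmf.
    Always <= 1; extinct states (i = 0) return 1 by convention.
    """
    if i == 0:
        return 1.0
    ratio = state.control.eps(i) / state.control.eps_sup
    pmf = one_step_pmf(state, i, j_max)
    numeric = pmf.mean() / (i * state.m * state.alpha * state.control.eps_sup)
    if abs(numeric - ratio) > verify_tol + j_max * pmf.tail_mass:
        raise AssertionError(f"supermartingale ratio mismatch: analytic {ratio}, from pmf {numeric}")
    return ratio


def submartingale_step_check(state: EnvironmentState, i: int) -> float:
    """One-step submartingale ratio eps(theta,i)/eps1 >= 1 for W_bar."""
    if i == 0:
        return 1.0
    eps1 = state.control.eps_inf
    if eps1 <= 0:
        raise ValueError("eps1 = 0: W_bar undefined")
    return state.control.eps(i) / eps1


# ---------------------------------------------------------------------------
# mean identity and Doob decomposition


@dataclass
class MeanIdentityReport:
    """Monte-Carlo check of E(W_hat_{n+1}) + sum_k E(W_hat_k * deficit_k) = 1."""

    estimate: float  # mean of the per-path statistic, should be 1
    se: float
    n: int
    reps: int
    passed: bool  # |estimate - 1| <= 4 se

    @property
    def deviation_sigmas(self) -> float:
        return abs(self.estimate - 1.0) / self.se if self.se > 0 else 0.0


def _deficit_matrix(ens: EnsembleResult, law: EnvironmentLaw) -> np.ndarray:
    """(reps, n) matrix of participation deficits (eps(xi_k) - eps(xi_k, Z_k)) / eps(xi_k)."""
    reps, n = ens.env_indices.shape
    out = np.zeros((reps, n))
    for s_idx, st in enumerate(law.states):
        mask = ens.env_indices == s_idx
        if not mask.any():
            continue
        z_here = ens.Z[:, :n][mask]
        eps_z = _eps_vec(st, z_here)
        deficit = np.where(z_here > 0, (st.control.eps_sup - eps_z) / st.control.eps_sup, 0.0)
        out[mask] = deficit
    return out


def mean_identity_check(
    law: EnvironmentLaw, n0: int, n: int, reps: int, seed, mode: str = "compound", cap: int = 10**12
) -> MeanIdentityReport:
    """Check the exact mean identity for W_hat by Monte Carlo.

    Iterating the one-step conditional mean gives, exactly,
    E(W_hat_{n+1}) = 1 - sum_{k<=n} E(W_hat_k * (eps(xi_k) - eps(xi_k,Z_k))/eps(xi_k)).
    The per-path statistic W_hat_{n+1} + sum_k W_hat_k * deficit_k therefore has
    expectation exactly 1; the check requires agreement within 4 MC standard
    errors.  The population cap defaults high: a frozen (capped) path would
    bias the identity, so exact integer growth matters more than speed here.
    """
    ens = simulate_ensemble(law, n0, n + 1, reps, seed, mode=mode, cap=cap)
    w_hat = ensemble_normalized(ens, law, "sup")
    deficit = _deficit_matrix(ens, law)
    stat = w_hat[:, n + 1] + np.sum(w_hat[:, : n + 1] * deficit[:, : n + 1], axis=1)
    est = float(stat.mean())
    se = float(stat.std(ddof=1) / math.sqrt(reps))
    return MeanIdentityReport(estimate=est, se=se, n=n, reps=reps, passed=abs(est - 1.0) <= 4 * se)


def doob_decomposition(ens: EnsembleResult, law: EnvironmentLaw) -> tuple[np.ndarray, np.ndarray]:
    """Per-path supermartingale W_hat and its Doob increasing process T_n.

    T_n = sum_{i<n} W_hat_i * (eps(xi_i) - eps(xi_i, Z_i)) / eps(xi_i); the
    compensated process W_hat_n + T_n is a martingale.
    """
    w_hat = ensemble_normalized(ens, law, "sup")
    deficit = _deficit_matrix(ens, law)
    increments = w_hat[:, :-1] * deficit
    T = np.concatenate([np.zeros((ens.reps, 1)), np.cumsum(increments, axis=1)], axis=1)
    return w_hat, T


# ---------------------------------------------------------------------------
# L2 bound and condition series


@dataclass
class L2BoundReport:
    bound: float  # may be inf
    partial: np.ndarray  # partial bounds vs n
    verdict: str  # converged-to-finite | diverging | inapplicable


def l2_bound(law: EnvironmentLaw, n0: int, n: int | None = None) -> L2BoundReport:
    """Analytic L2 bound for the supermartingale on a single-state law.

    E(W_hat_{n+1}^2) <= 1 + sum_i m2/(S_i alpha eps m^2) + sum_i delta2/(S_i^2 eps^2)
    with S_i = N0 (m alpha eps)^i deterministic.  With n = None the geometric
    series is summed to infinity when the growth factor exceeds 1.
    """
    if len(law.states) != 1:
        raise ValueError("l2_bound requires a single-state law (deterministic S_i)")
    st = law.states[0]
    eps, d2 = st.control.eps_sup, st.control.delta2_sup
    if not math.isfinite(d2):
        return L2BoundReport(bound=math.inf, partial=np.array([]), verdict="inapplicable")
    g = st.m * st.alpha * eps  # per-step growth factor
    a1 = st.m2 / (n0 * st.alpha * eps * st.m**2)  # i = 0 term of the first series
    a2 = d2 / (n0**2 * eps**2)
    if n is None:
        if g <= 1.0:
            return L2BoundReport(bound=math.inf, partial=np.array([]), verdict="diverging")
        bound = 1.0 + a1 * g / (g - 1.0) + a2 * g**2 / (g**2 - 1.0)
        return L2BoundReport(bound=float(bound), partial=np.array([bound]), verdict="converged-to-finite")
    i = np.arange(n + 1)
    terms = a1 * g**-i.astype(float) + a2 * (g**2) ** -i.astype(float)
    partial = 1.0 + np.cumsum(terms)
    verdict = "converged-to-finite" if g > 1.0 else "diverging"
    return L2BoundReport(bound=float(partial[-1]), partial=partial, verdict=verdict)


@dataclass
class ConditionReport:
    """Finite numerical certificate for one sufficient-condition series."""

    theorem: str
    terms: np.ndarray
    partial: np.ndarray
    verdict: str  # converged-to-finite | diverging | inconclusive
    detail: str = ""


def _ratio_verdict(terms: np.ndarray, window: int = 10) -> str:
    t = np.asarray(terms, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        return "inconclusive"
    if np.all(t[-min(window, t.size) :] == 0.0):
        return "converged-to-finite"
    tail = t[-min(window + 1, t.size) :]
    nz = tail[tail > 0]
    if nz.size < 2:
        return "inconclusive"
    ratios = nz[1:] / nz[:-1]
    r = float(np.max(ratios))
    if r < RATIO_CONVERGING:
        return "converged-to-finite"
    if float(np.min(ratios)) > RATIO_DIVERGING:
        return "diverging"
    if t[-1] > 1e-10:
        # ratio test indecisive but terms do not vanish: series diverges
        return "diverging"
    return "inconclusive"


def series_conditions(law: EnvironmentLaw, n0: int, n_terms: int = 50) -> list[ConditionReport]:
    """Evaluate the hypothesis series of the L1/L2 convergence theorems.

    Expectations over the environment are exact: because the xi_k are i.i.d.
    and S_i depends only on xi_0..xi_{i-1}, terms factor as
    E[g(xi_i)/S_i^p] = E[g] * E[(m alpha eps)^-p]^i / N0^p.
    """
    probs = law.probs
    m = np.array([s.m for s in law.states])
    m2 = np.array([s.m2 for s in law.states])
    alpha = np.array([s.alpha for s in law.states])
    eps = np.array([s.control.eps_sup for s in law.states])
    eps1 = np.array([s.control.eps_inf for s in law.states])
    d2 = np.array([s.control.delta2_sup for s in law.states])
    g = m * alpha * eps
    i = np.arange(n_terms, dtype=float)

    reports: list[ConditionReport] = []

    # L2-boundedness / L1-convergence series for the supermartingale
    e_inv = float(np.dot(probs, 1.0 / g))
    e_inv2 = float(np.dot(probs, 1.0 / g**2))
    t1 = float(np.dot(probs, m2 / (m**2 * alpha * eps))) / n0 * e_inv**i
    reports.append(
        ConditionReport("supermartingale_L2_offspring", t1, np.cumsum(t1), _ratio_verdict(t1),
                        "sum_i E[m2 / (S_i m^2 alpha eps)]")
    )
    if np.all(np.isfinite(d2)):
        t2 = float(np.dot(probs, d2 / eps**2)) / n0**2 * e_inv2**i
        verdict2, detail2 = _ratio_verdict(t2), "sum_i E[delta2 / (S_i^2 eps^2)]"
    else:
        t2, verdict2 = np.full(n_terms, math.inf), "diverging"
        detail2 = "delta2_sup = +inf for some state"
    reports.append(ConditionReport("supermartingale_L2_control", t2, np.cumsum(t2), verdict2, detail2))

    # L2-convergence series: sqrt of second moment of the relative eps spread,
    # plus square-rooted cumulative versions of the two series above
    spread2 = float(np.dot(probs, ((eps - eps1) / eps) ** 2))
    t3 = np.full(n_terms, math.sqrt(spread2))
    reports.append(
        ConditionReport("L2_convergence_spread", t3, np.cumsum(t3),
                        "converged-to-finite" if spread2 == 0.0 else "diverging",
                        "sum_i sqrt(E[((eps - eps1)/eps)^2]); constant terms")
    )
    t4 = np.sqrt(np.concatenate([[0.0], np.cumsum(t1)[:-1]]))
    reports.append(ConditionReport("L2_convergence_offspring_sqrt", t4, np.cumsum(t4), _ratio_verdict(np.diff(np.cumsum(t4), prepend=0.0)),
                                   "sum_i sqrt(sum_{j<i} E[m2/(S_j m^2 alpha eps)])"))
    if np.all(np.isfinite(d2)):
        t5 = np.sqrt(np.concatenate([[0.0], np.cumsum(t2)[:-1]]))
        v5 = _ratio_verdict(np.diff(np.cumsum(t5), prepend=0.0))
    else:
        t5, v5 = np.full(n_terms, math.inf), "diverging"
    reports.append(ConditionReport("L2_convergence_control_sqrt", t5, np.cumsum(t5), v5,
                                   "sum_i sqrt(sum_{j<i} E[delta2/(S_j^2 eps^2)])"))

    # submartingale mean bound: partial products E[prod_k eps/eps1] = (E[eps/eps1])^n
    if np.any(eps1 <= 0):
        reports.append(ConditionReport("submartingale_mean_bound", np.array([]), np.array([]), "inconclusive", "eps1 = 0"))
    else:
        e_ratio = float(np.dot(probs, eps / eps1))
        prods = e_ratio ** np.arange(1, n_terms + 1, dtype=float)
        if e_ratio <= 1.0 + 1e-12:
            verdict = "converged-to-finite"
        else:
            verdict = "diverging"
        reports.append(ConditionReport("submartingale_mean_bound", prods, prods, verdict,
                                       f"E[eps/eps1] = {e_ratio:.6g}; partial products"))
    return reports


# ---------------------------------------------------------------------------
# nondegeneracy (envelope) condition


def default_envelope(state: EnvironmentState, k_grid: int = 512):
    """Default nondecreasing minorant phi of k -> eps(theta, k) with x*phi(x) convex.

    Kernel families with a closed-form real extension of the participation
    rate (identity, binomial thinning, random emigration) supply it exactly.
    Otherwise phi is the piecewise-linear interpolation of the eps sequence
    on [1, k_grid] (constant eps(theta,1) below, clamped at eps(theta,k_grid)
    above); the clamp makes the convexity certificate valid only up to
    k_grid, which the caller checks numerically.
    """
    exact = state.control.eps_envelope()
    if exact is not None:
        return exact
    ks = np.arange(1, k_grid + 1)
    vals = np.array([state.control.eps(int(k)) for k in ks])
    if np.any(np.diff(vals) < -1e-12):
        raise ValueError(f"state {state.label}: eps(theta, k) not nondecreasing; no default envelope")

    def phi(x):
        return np.interp(np.asarray(x, dtype=float), ks.astype(float), vals)

    return phi


def _check_x_phi_convex(phi, x_max: float, grid: int = 400) -> bool:
    x = np.linspace(1e-6, max(x_max, 2.0), grid)
    y = x * np.asarray(phi(x), dtype=float)
    d2 = np.diff(y, 2)
    return bool(np.all(d2 >= -1e-8 * max(1.0, np.max(np.abs(y)))))


def nondegeneracy_condition(
    law: EnvironmentLaw,
    n0: int,
    n_terms: int = 200,
    envelopes: dict[str, object] | None = None,
    k_check: int = 256,
    seed=0,
    mc_reps: int = 4000,
) -> ConditionReport:
    """Certificate for P(W_hat > 0) > 0 via the envelope product condition.

    Evaluates partial products of E[ phi_{xi_i}(N0 prod_{j<i} m alpha eps1) / eps(xi_i) ],
    where phi is a nondecreasing minorant of the participation-rate sequence
    with x*phi(x) convex.  Products stabilizing above 0 certify a nondegenerate
    limit; decay toward 0 is inconclusive.  Exact for single-state laws,
    Monte Carlo over environment sequences otherwise.
    """
    for st in law.states:
        vals = [st.control.eps(k) for k in range(1, k_check + 1)]
        if np.any(np.diff(vals) < -1e-12):
            return ConditionReport("nondegeneracy_envelope", np.array([]), np.array([]), "theorem_inapplicable",
                                   f"state {st.label}: eps(theta, k) decreasing in k")
    if envelopes is None:
        envelopes = {st.label: default_envelope(st) for st in law.states}
    lf_inf = np.array([math.log(st.m * st.alpha * st.control.eps_inf) for st in law.states])
    eps_sup = np.array([st.control.eps_sup for st in law.states])

    if len(law.states) == 1:
        st = law.states[0]
        phi = envelopes[st.label]
        args = n0 * np.exp(lf_inf[0] * np.arange(n_terms))
        if not _check_x_phi_convex(phi, float(min(args.max(), 512.0))):
            return ConditionReport("nondegeneracy_envelope", np.array([]), np.array([]), "inconclusive",
                                   "x * phi(x) failed the numeric convexity check")
        terms = np.asarray(phi(args), dtype=float) / eps_sup[0]
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(law.states), size=(mc_reps, n_terms), p=law.probs)
        log_args = math.log(n0) + np.concatenate(
            [np.zeros((mc_reps, 1)), np.cumsum(lf_inf[idx], axis=1)[:, :-1]], axis=1
        )
        per = np.empty((mc_reps, n_terms))
        for s_idx, st in enumerate(law.states):
            mask = idx == s_idx
            per[mask] = np.asarray(envelopes[st.label](np.exp(log_args[mask])), dtype=float) / eps_sup[s_idx]
        terms = per.mean(axis=0)
    partial = np.cumprod(terms)
    deficits = np.maximum(1.0 - terms, 0.0)
    deficits[deficits < 1e-12] = 0.0  # below float resolution of 1 - phi/eps
    stable = partial[-1] > 1e-6 and _ratio_verdict(deficits) == "converged-to-finite"
    verdict = "nondegenerate" if stable else "inconclusive"
    return ConditionReport("nondegeneracy_envelope", terms, partial, verdict,
                           f"final partial product {partial[-1]:.6g}")


# ---------------------------------------------------------------------------
# r statistic and surviving-path diagnostic


def r_statistic(state: EnvironmentState, k: int, j_max: int = 4096, tail_tol: float = 1e-6) -> float:
    """Relative L1 step deviation r_k = E|Z' - k eps1 m alpha| / k at size k (exact)."""
    if k < 1:
        raise ValueError("r_k is defined for k >= 1")
    pmf = one_step_pmf(state, k, j_max)
    if pmf.tail_mass > tail_tol:
        raise ValueError(f"truncation tail {pmf.tail_mass:.3g} above {tail_tol:g}; increase j_max")
    target = k * state.control.eps_inf * state.m * state.alpha
    return float(np.sum(np.abs(pmf.support - target) * pmf.probs)) / k


def r_nonincreasing(state: EnvironmentState, ks=(1, 2, 4, 8, 16, 32), j_max: int = 4096) -> bool:
    """Probe whether the r_k sequence is nonincreasing over a grid of sizes."""
    vals = [r_statistic(state, k, j_max) for k in ks]
    return bool(np.all(np.diff(vals) <= 1e-12))


def surviving_path_condition(trajectory: Trajectory, law: EnvironmentLaw) -> tuple[np.ndarray, bool]:
    """Partial sums of sum_k (1 - eps(xi_k, Z_k)/eps(xi_k)) along one path.

    Diagnostic for the survival-set condition: on surviving paths the series
    should stay bounded.  Returns (partial sums, truncated_by_extinction).
    """
    n = trajectory.env_indices.size
    terms = np.zeros(n)
    for t in range(n):
        z = int(trajectory.Z[t])
        if z == 0:
            break
        st = law.states[trajectory.env_indices[t]]
        terms[t] = 1.0 - st.control.eps(z) / st.control.eps_sup
    truncated = trajectory.extinct_at is not None and trajectory.extinct_at <= n
    return np.cumsum(terms), truncated


# ---------------------------------------------------------------------------
# growth-rate recovery


def growth_rate_regression(ens: EnsembleResult, n_lo: int, n_hi: int) -> float:
    """Slope of log sample-mean(Z_n) on n over generations n_lo..n_hi.

    Recovers the per-step log growth factor log(m alpha eps) on scenarios
    where the mean grows geometrically.
    """
    n = np.arange(n_lo, n_hi + 1)
    y = np.log(ens.mean_Z[n_lo : n_hi + 1])
    slope = np.polyfit(n, y, 1)[0]
    return float(slope)
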