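"""Environment law for the branching process: states, pgfs, and summaries.

The process lives in an i.i.d. random environment.  Each environment state
``theta`` carries:

* a finite-support offspring pmf ``P_r(theta)``,
* a survival probability ``alpha(theta)`` (an individual escapes infection
  and reproduces with probability alpha; otherwise it leaves no offspring),
* a control kernel giving the law of the participation count ``phi(k)``.

Derived per-state scalars (offspring mean ``m``, second moment ``m2``,
participation rates ``eps``/``eps1``, control variance ``delta2``, dominator
``eta``) feed every downstream formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernels import DEFAULT_K_ANALYSIS, ControlKernel, _validate_pmf

__all__ = [
    "EnvironmentState",
    "EnvironmentLaw",
    "StateSummaries",
    "AssumptionReport",
    "offspring_pgf",
    "thinned_pgf",
    "summaries",
    "validate_assumptions",
    "sample_environment_sequence",
]


@dataclass
class EnvironmentState:
    """One environment value theta: offspring law, survival probability, control."""

    label: str
    offspring_pmf: np.ndarray
    alpha: float
    control: ControlKernel
    eta_override: float | None = None  # user-supplied dominating ratio

    def __post_init__(self):
        self.offspring_pmf = _validate_pmf(np.asarray(self.offspring_pmf, dtype=float), f"offspring pmf of {self.label}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"state {self.label}: alpha must be in (0, 1], got {self.alpha}")
        if self.eta_override is not None and self.eta_override < self.control.eta:
            raise ValueError(f"state {self.label}: eta override {self.eta_override} below the minimal dominator {self.control.eta}")

    # -- moments -----------------------------------------------------------

    @property
    def m(self) -> float:
        """Offspring mean m(theta)."""
        r = np.arange(self.offspring_pmf.size)
        return float(np.sum(r * self.offspring_pmf))

    @property
    def m2(self) -> float:
        """Offspring second moment m2(theta)."""
        r = np.arange(self.offspring_pmf.size)
        return float(np.sum(r * r * self.offspring_pmf))

    @property
    def var_thinned(self) -> float:
        """Var(X * I | theta) = m2 alpha - (m alpha)^2 for the thinned offspring."""
        return self.m2 * self.alpha - (self.m * self.alpha) ** 2

    @property
    def eta(self) -> float:
        return self.eta_override if self.eta_override is not None else self.control.eta

    def pgf(self, s):
        return offspring_pgf(self, s)

    def thinned_pgf(self, s):
        return thinned_pgf(self, s)


def offspring_pgf(state: EnvironmentState, s):
    """Offspring pgf f_theta(s) = sum_r P_r(theta) s^r for s in [0, 1]."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("pgf argument must lie in [0, 1]")
    out = np.polynomial.polynomial.polyval(s, state.offspring_pmf)
    return float(out) if out.ndim == 0 else out


def thinned_pgf(state: EnvironmentState, s):
    """pgf of the thinned offspring X*I: 1 - alpha + alpha * f_theta(s)."""
    return 1.0 - state.alpha + state.alpha * offspring_pgf(state, s)


@dataclass
class StateSummaries:
    """All per-state scalars used by the transition, extinction and limit formulas."""

    m: float
    m2: float
    var_thinned: float
    eps_sup: float
    eps_inf: float
    delta2_sup: float
    eta: float
    numeric_over_k: int | None  # K_analysis horizon when sup/inf are numeric, else None
    _state: EnvironmentState = field(repr=False, default=None)

    def eps_of_k(self, k: int) -> float:
        """Participation rate eps(theta, k) = E[phi(k)] / k, k >= 1."""
        return self._state.control.eps(k)

    def delta2_of_k(self, k: int) -> float:
        """Control variance delta2(theta, k) = Var(phi(k)), k >= 1."""
        return self._state.control.delta2(k)


def summaries(state: EnvironmentState, k_analysis: int = DEFAULT_K_ANALYSIS) -> StateSummaries:
    """Compute the scalar summaries of a state (closed form per kernel family)."""
    ctrl = state.control
    return StateSummaries(
        m=state.m,
        m2=state.m2,
        var_thinned=state.var_thinned,
        eps_sup=ctrl.eps_sup,
        eps_inf=ctrl.eps_inf,
        delta2_sup=ctrl.delta2_sup,
        eta=state.eta,
        numeric_over_k=getattr(ctrl, "k_analysis", None) if ctrl.summaries_numeric else None,
        _state=state,
    )


@dataclass
class EnvironmentLaw:
    """Finite i.i.d. environment law: states with sampling probabilities."""

    states: list[EnvironmentState]
    probs: np.ndarray

    def __post_init__(self):
        if not self.states:
            raise ValueError("environment law needs at least one state")
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        self.probs = _validate_pmf(np.asarray(self.probs, dtype=float), "environment probabilities")
        if self.probs.size != len(self.states):
            raise ValueError("probs length must match number of states")

    def __iter__(self):
        return iter(self.states)

    def __len__(self):
        return len(self.states)

    def state(self, label: str) -> EnvironmentState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"no state labelled {label!r}")

    def expectation(self, per_state_values) -> float:
        """Exact expectation over the environment of a per-state array."""
        return float(np.dot(self.probs, np.asarray(per_state_values, dtype=float)))


@dataclass
class AssumptionReport:
    """Per-state verdicts for the non-triviality assumptions."""

    entries: list[dict]

    @property
    def all_pass(self) -> bool:
        return all(e["status"] == "pass" for e in self.entries)

    @property
    def reduction_cases(self) -> list[str]:
        return sorted({e["state"] for e in self.entries if e["status"] == "warn"})


def validate_assumptions(law: EnvironmentLaw, k_probe: int = 50) -> AssumptionReport:
    """Check the non-triviality assumptions state by state.

    Two assumptions keep the model away from classical reductions:
    (1) 0 < P_0 + P_1 < 1 and the control is genuinely random
    (0 < Q(theta; k, k) < 1 for k >= 1); (2) 0 < alpha < 1.  Violations are
    reported as warnings, never raised: the boundary cases (identity control,
    alpha = 1) are exactly the classical models used as oracles.
    """
    entries: list[dict] = []
    for st in law.states:
        p01 = float(st.offspring_pmf[: min(2, st.offspring_pmf.size)].sum())
        entries.append(
            {
                "state": st.label,
                "check": "A1_offspring",
                "status": "pass" if 0.0 < p01 < 1.0 else "warn",
                "detail": f"P_0 + P_1 = {p01:.6g}",
            }
        )
        diag_ok = True
        for k in range(1, k_probe + 1):
            p = st.control.pmf(k)
            qkk = float(p[k]) if k < p.size else 0.0
            if not 0.0 < qkk < 1.0:
                diag_ok = False
                break
        entries.append(
            {
                "state": st.label,
                "check": "A1_control",
                "status": "pass" if diag_ok else "warn",
                "detail": "control random at every probed size" if diag_ok else f"Q(theta;{k},{k}) not in (0,1): reduction case",
            }
        )
        a2_ok = 0.0 < st.alpha < 1.0
        entries.append(
            {
                "state": st.label,
                "check": "A2_alpha",
                "status": "pass" if a2_ok else "warn",
                "detail": f"alpha = {st.alpha:.6g}" + ("" if a2_ok else " (alpha = 1 reduces to the uninfected controlled model)"),
            }
        )
    report = AssumptionReport(entries)
    for e in report.entries:
        if e["status"] == "warn":
            warnings.warn(f"{e['state']}/{e['check']}: {e['detail']}", stacklevel=2)
    return report


def sample_environment_sequence(law: EnvironmentLaw, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. environment state indices; reproducible under the seed."""
    if n < 0:
        raise ValueError("sequence length must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.choice(len(law.states), size=n, p=law.probs)
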