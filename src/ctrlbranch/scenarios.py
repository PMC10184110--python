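"""Built-in fixture scenarios spanning the interesting regimes.

Each scenario bundles an environment law, an initial size, default run
parameters, and expected-behaviour annotations (criterion sign, known fixed
points, exact means) that the analysis modules must reproduce; the
``selftest`` entry point re-derives every annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentLaw, EnvironmentState
from .extinction import extinction_criterion, iterate_mu
from .kernels import BinomialThinningKernel, EmigrationKernel, IdentityKernel
from .limits import nondegeneracy_condition
from .transition import propagate_distribution

__all__ = ["Scenario", "builtin_scenarios", "get_scenario", "selftest"]


@dataclass
class Scenario:
    name: str
    law: EnvironmentLaw
    n0: int
    horizon: int = 50
    reps: int = 10_000
    seed: int = 42
    annotations: dict = field(default_factory=dict)


def _theta1(alpha: float = 0.8, control=None, label: str = "theta1") -> EnvironmentState:
    return EnvironmentState(label, np.array([0.25, 0.25, 0.5]), alpha, control or IdentityKernel())


def _theta3(alpha: float = 0.8, control=None, label: str = "theta3") -> EnvironmentState:
    return EnvironmentState(label, np.array([0.2, 0.2, 0.6]), alpha, control or IdentityKernel())


def _em_kernel() -> EmigrationKernel:
    # random emigration: one individual leaves with probability 1/2
    return EmigrationKernel(np.array([0.5, 0.5]))


def builtin_scenarios() -> list[Scenario]:
    """The shipped fixture scenarios.

    * S1_critical — thinned mean m*alpha = 1 exactly (critical), identity control.
    * S2_subcritical — thinned mean 0.9; certain extinction, criterion log 0.9.
    * S3_supercritical_gw — single-state identity: a classical Galton-Watson
      process with thinned pgf 0.36 + 0.16 s + 0.48 s^2, extinction prob 3/4.
    * S4_two_state — mixed sub/supercritical environment, binomial thinning 0.9.
    * S5_emigration — strong offspring (m = 3) with random emigration, N0 = 2;
      supercritical with a nondegenerate normalized limit.
    * S6_reduction_alpha1 — alpha = 1, identity control: the classical
      uncontrolled, uninfected branching process in a random environment.
    """
    s1 = Scenario(
        "S1_critical",
        EnvironmentLaw([_theta1()], np.array([1.0])),
        n0=1,
        annotations={"criterion": 0.0, "mean_Z_constant": 1.0},
    )
    s2 = Scenario(
        "S2_subcritical",
        EnvironmentLaw([_theta1(alpha=0.72, label="theta2")], np.array([1.0])),
        n0=1,
        annotations={"criterion": math.log(0.9)},
    )
    s3 = Scenario(
        "S3_supercritical_gw",
        EnvironmentLaw([_theta3()], np.array([1.0])),
        n0=1,
        annotations={"criterion": math.log(1.12), "extinction_probability": 0.75},
    )
    s4 = Scenario(
        "S4_two_state",
        EnvironmentLaw(
            [
                _theta1(alpha=0.72, control=BinomialThinningKernel(0.9), label="theta2"),
                _theta3(control=BinomialThinningKernel(0.9)),
            ],
            np.array([0.5, 0.5]),
        ),
        n0=1,
        annotations={"criterion": 0.5 * (math.log(0.9) + math.log(1.12))},
    )
    s5 = Scenario(
        "S5_emigration",
        EnvironmentLaw(
            [EnvironmentState("theta_strong", np.array([0.1, 0.0, 0.3, 0.0, 0.6]), 0.8, _em_kernel())],
            np.array([1.0]),
        ),
        n0=2,
        annotations={"criterion": math.log(2 * 0.8 * 3.0), "nondegenerate": True},
    )
    s6 = Scenario(
        "S6_reduction_alpha1",
        EnvironmentLaw(
            [
                EnvironmentState("theta1_a1", np.array([0.25, 0.25, 0.5]), 1.0, IdentityKernel()),
                EnvironmentState("theta3_a1", np.array([0.2, 0.2, 0.6]), 1.0, IdentityKernel()),
            ],
            np.array([0.5, 0.5]),
        ),
        n0=1,
        annotations={"quenched_mean_is_product_of_m": True},
    )
    return [s1, s2, s3, s4, s5, s6]


def get_scenario(name: str) -> Scenario:
    for sc in builtin_scenarios():
        if sc.name == name:
            return sc
    raise KeyError(f"no built-in scenario named {name!r}; see `scenario list`")


def selftest(atol_criterion: float = 1e-12, atol_fixed_point: float = 1e-6) -> list[str]:
    """Re-derive every scenario annotation; returns a list of failures (empty = ok)."""
    failures: list[str] = []
    for sc in builtin_scenarios():
        ann = sc.annotations
        if "criterion" in ann:
            rep = extinction_criterion(sc.law, sc.n0)
            if abs(rep.expectation - ann["criterion"]) > atol_criterion:
                failures.append(f"{sc.name}: criterion {rep.expectation} != {ann['criterion']}")
        if "extinction_probability" in ann:
            st = sc.law.states[0]
            it = iterate_mu([st] * 400, sc.n0, 400)
            if abs(it.limit_estimate - ann["extinction_probability"]) > atol_fixed_point:
                failures.append(f"{sc.name}: mu limit {it.limit_estimate} != {ann['extinction_probability']}")
        if "mean_Z_constant" in ann:
            st = sc.law.states[0]
            dists = propagate_distribution([st] * 8, sc.n0, j_max=512)
            means = [d.mean() for d in dists]
            if any(abs(mu - ann["mean_Z_constant"]) > 1e-9 + 512 * d.tail_mass for mu, d in zip(means, dists)):
                failures.append(f"{sc.name}: propagated mean drifts from {ann['mean_Z_constant']}: {means}")
        if ann.get("nondegenerate"):
            rep = nondegeneracy_condition(sc.law, sc.n0)
            if rep.verdict != "nondegenerate":
                failures.append(f"{sc.name}: nondegeneracy verdict {rep.verdict!r}")
        if ann.get("quenched_mean_is_product_of_m"):
            # alpha = 1 + identity control: E(Z_n | xi) = N0 * prod m(xi_i) exactly
            idx = [0, 1, 1, 0, 1]
            seq = [sc.law.states[i] for i in idx]
            dists = propagate_distribution(seq, sc.n0, j_max=2048)
            expect = sc.n0 * np.cumprod([1.0] + [s.m for s in seq])
            for t, (d, e) in enumerate(zip(dists, expect)):
                if abs(d.mean() - e) > 1e-9 + 2048 * d.tail_mass:
                    failures.append(f"{sc.name}: quenched mean at t={t}: {d.mean()} != {e}")
                    break
    return failures
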