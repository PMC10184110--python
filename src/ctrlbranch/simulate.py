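"""Seeded Monte-Carlo simulation of the controlled, infection-thinned process.

One generation: the environment state xi_n is drawn (or fixed, for quenched
runs), the control picks phi_n(Z_n) participants, each participant survives
infection with probability alpha(xi_n), and survivors reproduce i.i.d. from
the offspring pmf.  Two sampling modes are provided and are equal in
distribution:

* ``per_individual`` — classify each of the phi participants jointly by
  (infection outcome, offspring count) in one multinomial draw;
* ``compound`` (default, faster) — draw survivors ~ Binomial(phi, alpha),
  then the offspring total of the survivors in one multinomial draw.

The ensemble engine is generation-synchronous and vectorized across
replicates; a single master seed makes the whole ensemble bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentLaw, EnvironmentState

__all__ = ["Trajectory", "EnsembleResult", "simulate_path", "simulate_ensemble", "quenched_ensemble"]

DEFAULT_POPULATION_CAP = 10**8


def _offspring_total(state: EnvironmentState, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized sum of `counts[i]` i.i.d. offspring draws, via multinomial."""
    r = np.arange(state.offspring_pmf.size)
    cells = rng.multinomial(counts, state.offspring_pmf)
    return cells @ r


def _step_state(state: EnvironmentState, z: np.ndarray, rng: np.random.Generator, mode: str):
    """Advance all replicates currently in `state`; returns (z_next, phi, survivors)."""
    phi = state.control.sample(z, rng)
    if mode == "compound":
        surv = rng.binomial(phi, state.alpha)
        z_next = _offspring_total(state, surv, rng)
    elif mode == "per_individual":
        # joint classification of each participant: dead (prob 1-alpha) or
        # survivor with offspring r (prob alpha * P_r)
        pvec = np.concatenate([[1.0 - state.alpha], state.alpha * state.offspring_pmf])
        pvec = pvec / pvec.sum()
        vals = np.concatenate([[0], np.arange(state.offspring_pmf.size)])
        cells = rng.multinomial(phi, pvec)
        z_next = cells @ vals
        surv = phi - cells[..., 0]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return z_next.astype(np.int64), phi.astype(np.int64), surv.astype(np.int64)


@dataclass
class Trajectory:
    """One realized path of (environment, Z_n, phi_n(Z_n), survivors)."""

    env_indices: np.ndarray  # length n, state index per generation step
    Z: np.ndarray  # length n+1
    phi: np.ndarray  # length n, participants in step n -> n+1
    survivors: np.ndarray  # length n, participants that escaped infection
    extinct_at: int | None
    overflow_at: int | None
    seed: object

    @property
    def extinct(self) -> bool:
        return self.extinct_at is not None


@dataclass
class EnsembleResult:
    """Replicated paths plus per-generation summary statistics."""

    Z: np.ndarray  # (reps, n+1) population sizes
    env_indices: np.ndarray  # (reps, n) state indices
    seed: object
    mode: str
    n0: int
    overflow_at: np.ndarray = None  # (reps,) generation of cap overflow, -1 if none
    extinction_frequency: np.ndarray = field(default=None)  # per generation
    mean_Z: np.ndarray = field(default=None)
    var_Z: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.extinction_frequency is None:
            self.extinction_frequency = (self.Z == 0).mean(axis=0)
        if self.mean_Z is None:
            self.mean_Z = self.Z.mean(axis=0)
        if self.var_Z is None:
            self.var_Z = self.Z.var(axis=0, ddof=1) if self.Z.shape[0] > 1 else np.zeros(self.Z.shape[1])

    @property
    def reps(self) -> int:
        return self.Z.shape[0]

    @property
    def horizon(self) -> int:
        return self.Z.shape[1] - 1

    def extinct_by(self, n: int) -> np.ndarray:
        return self.Z[:, n] == 0


def _run_ensemble(
    law: EnvironmentLaw,
    n0: int,
    n_max: int,
    reps: int,
    rng: np.random.Generator,
    mode: str,
    env_fixed: np.ndarray | None,
    cap: int,
    seed_record,
) -> EnsembleResult:
    if n0 < 1:
        raise ValueError("initial size must be >= 1")
    if n_max < 0 or reps < 1:
        raise ValueError("need n_max >= 0 and reps >= 1")
    Z = np.zeros((reps, n_max + 1), dtype=np.int64)
    Z[:, 0] = n0
    env = np.zeros((reps, n_max), dtype=np.int64)
    overflow_at = np.full(reps, -1, dtype=np.int64)
    z = Z[:, 0].copy()
    for t in range(n_max):
        if env_fixed is not None:
            idx = np.full(reps, env_fixed[t], dtype=np.int64)
        else:
            idx = rng.choice(len(law.states), size=reps, p=law.probs)
        env[:, t] = idx
        z_next = np.zeros(reps, dtype=np.int64)
        active = (z > 0) & (overflow_at < 0)
        for s in range(len(law.states)):
            sub = active & (idx == s)
            if not sub.any():
                continue
            zn, _, _ = _step_state(law.states[s], z[sub], rng, mode)
            z_next[sub] = zn
        frozen = overflow_at >= 0
        z_next[frozen] = z[frozen]
        newly_over = (z_next > cap) & ~frozen
        if newly_over.any():
            overflow_at[newly_over] = t + 1
        z = z_next
        Z[:, t + 1] = z
    return EnsembleResult(Z=Z, env_indices=env, seed=seed_record, mode=mode, n0=n0, overflow_at=overflow_at)


def simulate_path(
    law: EnvironmentLaw,
    n0: int,
    n_max: int,
    seed,
    mode: str = "compound",
    env_indices: np.ndarray | None = None,
    cap: int = DEFAULT_POPULATION_CAP,
) -> Trajectory:
    """Simulate a single trajectory; reproducible under the seed."""
    if n0 < 1 or n_max < 0:
        raise ValueError("need n0 >= 1 and n_max >= 0")
    rng = np.random.default_rng(seed)
    Z = np.zeros(n_max + 1, dtype=np.int64)
    Z[0] = n0
    env = np.zeros(n_max, dtype=np.int64)
    phi = np.zeros(n_max, dtype=np.int64)
    surv = np.zeros(n_max, dtype=np.int64)
    extinct_at = None
    overflow_at = None
    for t in range(n_max):
        if env_indices is not None:
            env[t] = env_indices[t]
        else:
            env[t] = rng.choice(len(law.states), p=law.probs)
        if Z[t] == 0 or overflow_at is not None:
            Z[t + 1] = Z[t]
            continue
        zn, ph, sv = _step_state(law.states[env[t]], Z[t : t + 1], rng, mode)
        Z[t + 1], phi[t], surv[t] = zn[0], ph[0], sv[0]
        if Z[t + 1] > cap and overflow_at is None:
            overflow_at = t + 1
        if Z[t + 1] == 0 and extinct_at is None:
            extinct_at = t + 1
    return Trajectory(env_indices=env, Z=Z, phi=phi, survivors=surv, extinct_at=extinct_at, overflow_at=overflow_at, seed=seed)


def simulate_ensemble(
    law: EnvironmentLaw,
    n0: int,
    n_max: int,
    reps: int,
    seed,
    mode: str = "compound",
    cap: int = DEFAULT_POPULATION_CAP,
) -> EnsembleResult:
    """Simulate `reps` independent annealed replicates (environments redrawn per path)."""
    rng = np.random.default_rng(seed)
    return _run_ensemble(law, n0, n_max, reps, rng, mode, None, cap, seed)


def quenched_ensemble(
    law: EnvironmentLaw,
    env_indices: np.ndarray,
    n0: int,
    reps: int,
    seed,
    mode: str = "compound",
    cap: int = DEFAULT_POPULATION_CAP,
) -> EnsembleResult:
    """Simulate replicates sharing one fixed environment sequence (quenched law)."""
    env_indices = np.asarray(env_indices, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return _run_ensemble(law, n0, len(env_indices), reps, rng, mode, env_indices, cap, seed)
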