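"""Exact one-step transition law and quenched distribution propagation.

Given environment state theta and current size i, the next size is
``Z' = sum_{l=1}^{phi(i)} X_l I_l``: draw the participation count phi(i)
from the control kernel, then add up phi(i) i.i.d. thinned offspring
variables X*I.  The one-step pmf is therefore a mixture over k of k-fold
convolutions of the thinned offspring pmf — mathematically identical to
the textbook enumeration over all offspring/indicator tuples, but
polynomial instead of exponential.

All pmfs are truncated at a cap ``J_max`` with the lost mass tracked
explicitly as ``tail_mass`` (never silently renormalized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import EnvironmentState

__all__ = [
    "SizedPmf",
    "thinned_offspring_pmf",
    "convolve_power",
    "one_step_pmf",
    "conditional_mean",
    "conditional_variance",
    "propagate_distribution",
]

DEFAULT_J_MAX = 4096


@dataclass
class SizedPmf:
    """Finite pmf over population sizes 0..J_max plus tracked tail mass."""

    probs: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if -1e-12 < self.tail_mass < 0.0:  # float noise from 1 - sum
            self.tail_mass = 0.0
        total = self.probs.sum() + self.tail_mass
        if self.probs.ndim != 1 or np.any(self.probs < 0) or self.tail_mass < 0 or not (1 - 1e-9 <= total <= 1 + 1e-9):
            raise ValueError(f"invalid SizedPmf: retained {self.probs.sum():.12g}, tail {self.tail_mass:.3g}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs))

    def var(self) -> float:
        mu = self.mean()
        return float(np.sum((self.support - mu) ** 2 * self.probs))

    def trimmed(self) -> "SizedPmf":
        """Drop trailing zeros (cosmetic; same distribution)."""
        nz = np.flatnonzero(self.probs)
        end = (nz[-1] + 1) if nz.size else 1
        return SizedPmf(self.probs[:end].copy(), self.tail_mass)


def _truncate(vec: np.ndarray, j_max: int) -> tuple[np.ndarray, float]:
    if vec.size > j_max + 1:
        lost = float(vec[j_max + 1 :].sum())
        return vec[: j_max + 1], lost
    return vec, 0.0


def thinned_offspring_pmf(state: EnvironmentState) -> SizedPmf:
    """pmf of the thinned offspring X*I: mass 1-alpha+alpha*P_0 at 0, alpha*P_r at r>=1."""
    p = state.alpha * state.offspring_pmf.copy()
    p[0] += 1.0 - state.alpha
    return SizedPmf(p)


def convolve_power(pmf: SizedPmf, k: int, j_max: int = DEFAULT_J_MAX) -> SizedPmf:
    """Exact k-fold self-convolution truncated at j_max (binary exponentiation)."""
    if j_max < 0:
        raise ValueError("j_max must be >= 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    result = np.array([1.0])
    base = pmf.probs
    while k:
        if k & 1:
            result = np.convolve(result, base)
            result, _ = _truncate(result, j_max)
        k >>= 1
        if k:
            base = np.convolve(base, base)
            base, _ = _truncate(base, j_max)
    # retained mass can only shrink under truncation, so 1 - sum bounds all loss
    return SizedPmf(result, 1.0 - float(result.sum()))


def one_step_pmf(state: EnvironmentState, i: int, j_max: int = DEFAULT_J_MAX) -> SizedPmf:
    """Exact law of Z_{n+1} given Z_n = i in environment state theta.

    Mixture over the participation count k of the k-fold convolution of the
    thinned offspring pmf, weighted by the control kernel Q(theta; i, k).
    Size 0 is absorbing.
    """
    if i < 0:
        raise ValueError("current size must be >= 0")
    if i == 0:
        return SizedPmf(np.array([1.0]))
    q = state.control.pmf(i)
    y = thinned_offspring_pmf(state).probs
    out = np.zeros(1)
    power = np.array([1.0])  # y^{*k}, built incrementally
    for k, qk in enumerate(q):
        if k > 0:
            power = np.convolve(power, y)
            power, _ = _truncate(power, j_max)
        if qk > 0.0:
            if power.size > out.size:
                out = np.pad(out, (0, power.size - out.size))
            out[: power.size] += qk * power
    out, _ = _truncate(out, j_max)
    return SizedPmf(out, 1.0 - float(out.sum()))


def conditional_mean(state: EnvironmentState, i: int) -> float:
    """E(Z_{n+1} | Z_n = i, theta) = i * m * alpha * eps(theta, i)."""
    if i < 0:
        raise ValueError("current size must be >= 0")
    if i == 0:
        return 0.0
    return i * state.m * state.alpha * state.control.eps(i)


def conditional_variance(state: EnvironmentState, i: int) -> float:
    """Var(Z_{n+1} | Z_n = i, theta) = i*eps(theta,i)*Var(XI) + m^2 alpha^2 delta2(theta,i)."""
    if i < 0:
        raise ValueError("current size must be >= 0")
    if i == 0:
        return 0.0
    return i * state.control.eps(i) * state.var_thinned + (state.m * state.alpha) ** 2 * state.control.delta2(i)


def propagate_distribution(
    env_sequence: list[EnvironmentState],
    n0: int,
    n: int | None = None,
    j_max: int = DEFAULT_J_MAX,
) -> list[SizedPmf]:
    """Exact quenched law of Z_0..Z_n along a fixed environment sequence.

    Per step: mix the control kernel over the current size distribution to
    get the law of the participation count, then convolve in the thinned
    offspring pmf once per participation unit.  Tail mass is a valid upper
    bound on lost probability and is nondecreasing in t.
    """
    if n0 < 1:
        raise ValueError("initial size must be >= 1")
    if n is None:
        n = len(env_sequence)
    if n > len(env_sequence):
        raise ValueError("environment sequence shorter than horizon")
    if n0 > j_max:
        raise ValueError(f"initial size {n0} exceeds cap j_max={j_max}; increase j_max")
    z0 = np.zeros(n0 + 1)
    z0[n0] = 1.0
    out = [SizedPmf(z0)]
    for t in range(n):
        state = env_sequence[t]
        cur = out[-1]
        # law of K = phi(Z_t): mixture of kernel pmfs over current sizes
        k_pmf = np.zeros(1)
        k_pmf[0] = float(cur.probs[0]) if cur.probs.size else 0.0
        for i in range(1, cur.probs.size):
            pi = cur.probs[i]
            if pi == 0.0:
                continue
            qk = state.control.pmf(i)
            if qk.size > k_pmf.size:
                k_pmf = np.pad(k_pmf, (0, qk.size - k_pmf.size))
            k_pmf[: qk.size] += pi * qk
        # Z_{t+1} = sum of K iid thinned offspring
        y = thinned_offspring_pmf(state).probs
        nxt = np.zeros(1)
        power = np.array([1.0])
        for k in range(k_pmf.size):
            if k > 0:
                power = np.convolve(power, y)
                power, _ = _truncate(power, j_max)
            if k_pmf[k] > 0.0:
                if power.size > nxt.size:
                    nxt = np.pad(nxt, (0, power.size - nxt.size))
                nxt[: power.size] += k_pmf[k] * power
        nxt, _ = _truncate(nxt, j_max)
        out.append(SizedPmf(nxt, 1.0 - float(nxt.sum())))
    return out
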