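"""Random control kernels: the law of the participation count phi(k).

A control kernel gives, for every current population size ``k``, the
distribution ``Q(theta; k, .)`` of the number of individuals that take part
in reproduction.  Size 0 is always absorbing (``Q(theta; 0, 0) = 1``).

Each kernel exposes its pmf, exact first two moments, and the scalar
summaries used throughout the analysis:

* ``eps(k) = E[phi(k)] / k`` — the participation rate at size ``k``;
* ``eps_sup`` / ``eps_inf`` — sup / inf of ``eps(k)`` over ``k >= 1``;
* ``delta2(k) = Var(phi(k))`` and ``delta2_sup``;
* ``eta`` — the minimal deterministic dominator ``sup_k max-support(phi(k))/k``
  (may be ``inf``), used by the certain-extinction criterion.

Closed forms are used where the kernel family admits them; the tabulated
kernel falls back to a numeric scan over ``k <= K_analysis``.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod

import numpy as np

__all__ = [
    "ControlKernel",
    "IdentityKernel",
    "BinomialThinningKernel",
    "EmigrationKernel",
    "ImmigrationKernel",
    "TabulatedKernel",
    "kernel_from_config",
]

#: horizon for numeric sup/inf scans on kernels without closed forms
DEFAULT_K_ANALYSIS = 512


def _validate_pmf(p: np.ndarray, what: str, tol: float = 1e-12, hard: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError(f"{what}: pmf must be a non-empty 1-d vector")
    if np.any(p < 0):
        raise ValueError(f"{what}: negative probability")
    drift = abs(p.sum() - 1.0)
    if drift > hard:
        raise ValueError(f"{what}: pmf sums to {p.sum():.12g}, drift {drift:.3g} exceeds {hard:g}")
    if drift > tol:
        # refuse silent renormalization above the soft tolerance is the hard
        # branch above; within [tol, hard] we renormalize explicitly
        p = p / p.sum()
    return p


class ControlKernel(ABC):
    """Law of phi(k) given the environment state."""

    kind: str

    @abstractmethod
    def pmf(self, k: int) -> np.ndarray:
        """Probability vector of phi(k) over 0..max-support; k=0 -> point mass at 0."""

    @abstractmethod
    def mean(self, k: int) -> float:
        ...

    @abstractmethod
    def var(self, k: int) -> float:
        ...

    @abstractmethod
    def max_support(self, k: int) -> int:
        ...

    @abstractmethod
    def sample(self, k: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vectorized draw of phi(k_i) for an integer array ``k``."""

    # --- participation-rate summaries -------------------------------------

    def eps(self, k: int) -> float:
        if k < 1:
            raise ValueError("eps(k) is defined for k >= 1 only")
        return self.mean(k) / k

    def delta2(self, k: int) -> float:
        if k < 1:
            raise ValueError("delta2(k) is defined for k >= 1 only")
        return self.var(k)

    @property
    @abstractmethod
    def eps_sup(self) -> float:
        ...

    @property
    @abstractmethod
    def eps_inf(self) -> float:
        ...

    @property
    @abstractmethod
    def delta2_sup(self) -> float:
        ...

    @property
    @abstractmethod
    def eta(self) -> float:
        ...

    @property
    def summaries_numeric(self) -> bool:
        """True when sup/inf summaries come from a finite numeric scan."""
        return False

    def eps_envelope(self):
        """Real-argument nondecreasing minorant of k -> eps(k), or None.

        When the kernel family admits a closed-form extension phi(x) with
        phi(j) <= eps(j) at integers, phi >= eps(1), and x*phi(x) convex,
        return it (vectorized callable); otherwise None and callers fall
        back to a piecewise-linear interpolation.
        """
        return None

    def is_identity(self) -> bool:
        return isinstance(self, IdentityKernel)

    def to_config(self) -> dict:
        return {"kind": self.kind}


class IdentityKernel(ControlKernel):
    """phi(k) = k: every individual participates (classical, uncontrolled)."""

    kind = "identity"

    def pmf(self, k: int) -> np.ndarray:
        out = np.zeros(k + 1)
        out[k] = 1.0
        return out

    def mean(self, k: int) -> float:
        return float(k)

    def var(self, k: int) -> float:
        return 0.0

    def max_support(self, k: int) -> int:
        return k

    def sample(self, k, rng):
        return np.asarray(k, dtype=np.int64).copy()

    eps_sup = property(lambda self: 1.0)
    eps_inf = property(lambda self: 1.0)
    delta2_sup = property(lambda self: 0.0)
    eta = property(lambda self: 1.0)

    def eps_envelope(self):
        return lambda x: np.ones_like(np.asarray(x, dtype=float))


class BinomialThinningKernel(ControlKernel):
    """phi(k) ~ Binomial(k, p): each individual participates independently."""

    kind = "binomial_thinning"

    def __init__(self, p: float):
        if not 0.0 < p <= 1.0:
            raise ValueError("binomial thinning needs 0 < p <= 1")
        self.p = float(p)

    def pmf(self, k: int) -> np.ndarray:
        from scipy.stats import binom

        return binom.pmf(np.arange(k + 1), k, self.p)

    def mean(self, k: int) -> float:
        return k * self.p

    def var(self, k: int) -> float:
        return k * self.p * (1.0 - self.p)

    def max_support(self, k: int) -> int:
        return k

    def sample(self, k, rng):
        k = np.asarray(k, dtype=np.int64)
        return rng.binomial(k, self.p)

    eps_sup = property(lambda self: self.p)
    eps_inf = property(lambda self: self.p)

    @property
    def delta2_sup(self) -> float:
        # Var(phi(k)) = k p (1-p) is unbounded in k unless p = 1
        return 0.0 if self.p == 1.0 else math.inf

    eta = property(lambda self: 1.0)

    def eps_envelope(self):
        return lambda x: np.full_like(np.asarray(x, dtype=float), self.p)

    def to_config(self) -> dict:
        return {"kind": self.kind, "p": self.p}


class EmigrationKernel(ControlKernel):
    """phi(k) = (k - E)^+ for a random removal count E with finite pmf.

    eps(k) = 1 - E[min(E, k)]/k is nondecreasing in k with limit 1, so
    eps_inf = eps(1) = P(E = 0) and eps_sup = 1.  For k >= max-support(E)
    the variance equals Var(E); delta2_sup is the max over the initial ramp.
    """

    kind = "random_emigration"

    def __init__(self, removal_pmf):
        self.removal_pmf = _validate_pmf(np.asarray(removal_pmf, dtype=float), "removal pmf")
        self._emax = int(np.flatnonzero(self.removal_pmf)[-1])
        self._evals = np.arange(self.removal_pmf.size)

    def pmf(self, k: int) -> np.ndarray:
        out = np.zeros(k + 1)
        phi = np.maximum(k - self._evals, 0)
        np.add.at(out, phi, self.removal_pmf)
        return out

    def mean(self, k: int) -> float:
        return float(np.sum(np.maximum(k - self._evals, 0) * self.removal_pmf))

    def var(self, k: int) -> float:
        phi = np.maximum(k - self._evals, 0)
        mu = np.sum(phi * self.removal_pmf)
        return float(np.sum((phi - mu) ** 2 * self.removal_pmf))

    def max_support(self, k: int) -> int:
        return k

    def sample(self, k, rng):
        k = np.asarray(k, dtype=np.int64)
        e = rng.choice(self._evals, size=k.shape, p=self.removal_pmf)
        return np.maximum(k - e, 0)

    eps_sup = property(lambda self: 1.0)

    @property
    def eps_inf(self) -> float:
        # eps(k) nondecreasing: min(E,k)/k is nonincreasing in k pointwise
        return float(self.removal_pmf[0])

    @property
    def delta2_sup(self) -> float:
        ks = range(1, self._emax + 2)
        return max((self.var(k) for k in ks), default=0.0)

    eta = property(lambda self: 1.0)

    def eps_envelope(self):
        # real extension 1 - E[min(E, x)]/x: equals eps at integers,
        # constant eps(1) = P(E=0) on (0, 1], and x*phi(x) = x - E[min(E,x)]
        # is convex since min(e, x) is concave in x
        evals, pmf = self._evals, self.removal_pmf

        def phi(x):
            x = np.asarray(x, dtype=float)
            expected_min = np.sum(pmf[:, None] * np.minimum(evals[:, None], x.ravel()[None, :]), axis=0)
            return (1.0 - expected_min / np.maximum(x.ravel(), 1e-300)).reshape(x.shape)

        return phi

    def to_config(self) -> dict:
        return {"kind": self.kind, "removal_pmf": {str(i): float(p) for i, p in enumerate(self.removal_pmf) if p > 0}}


class ImmigrationKernel(ControlKernel):
    """phi(k) = k + M for a random addition count M with finite pmf.

    eps(k) = 1 + E[M]/k decreases to 1; eps_sup is attained at k = 1 and
    eps_inf = 1 (infimum, not attained when E[M] > 0).  eta = 1 + max M.
    """

    kind = "random_immigration"

    def __init__(self, addition_pmf):
        self.addition_pmf = _validate_pmf(np.asarray(addition_pmf, dtype=float), "addition pmf")
        self._mmax = int(np.flatnonzero(self.addition_pmf)[-1])
        self._mvals = np.arange(self.addition_pmf.size)
        self._mmean = float(np.sum(self._mvals * self.addition_pmf))
        self._mvar = float(np.sum((self._mvals - self._mmean) ** 2 * self.addition_pmf))

    def pmf(self, k: int) -> np.ndarray:
        if k == 0:  # extinction stays absorbing: no immigration into size 0
            return np.array([1.0])
        out = np.zeros(k + self._mmax + 1)
        out[k : k + self.addition_pmf.size] = self.addition_pmf
        return out

    def mean(self, k: int) -> float:
        return k + self._mmean if k > 0 else 0.0

    def var(self, k: int) -> float:
        return self._mvar if k > 0 else 0.0

    def max_support(self, k: int) -> int:
        return k + self._mmax if k > 0 else 0

    def sample(self, k, rng):
        k = np.asarray(k, dtype=np.int64)
        m = rng.choice(self._mvals, size=k.shape, p=self.addition_pmf)
        out = k + m
        out[k == 0] = 0  # size 0 stays absorbing
        return out

    @property
    def eps_sup(self) -> float:
        return 1.0 + self._mmean

    eps_inf = property(lambda self: 1.0)
    delta2_sup = property(lambda self: float(self._mvar))

    @property
    def eta(self) -> float:
        return 1.0 + self._mmax

    def to_config(self) -> dict:
        return {"kind": self.kind, "addition_pmf": {str(i): float(p) for i, p in enumerate(self.addition_pmf) if p > 0}}


class TabulatedKernel(ControlKernel):
    """Explicit pmf of phi(k) per size k; summaries scanned over k <= K_analysis."""

    kind = "tabulated"

    def __init__(self, table: dict[int, np.ndarray], k_analysis: int | None = None):
        self.table = {int(k): _validate_pmf(np.asarray(v, dtype=float), f"phi({k}) pmf") for k, v in table.items()}
        if 0 in self.table:
            p0 = self.table[0]
            if not (p0.size >= 1 and p0[0] == 1.0 and p0.sum() == 1.0):
                raise ValueError("phi(0) must be a point mass at 0 (extinction is absorbing)")
        self.k_analysis = int(k_analysis) if k_analysis is not None else max(self.table.keys(), default=1)
        missing = [k for k in range(1, self.k_analysis + 1) if k not in self.table]
        if missing:
            raise ValueError(f"tabulated kernel missing pmf for k={missing[0]} (needed up to K_analysis={self.k_analysis})")

    def pmf(self, k: int) -> np.ndarray:
        if k == 0:
            return np.array([1.0])
        try:
            return self.table[k]
        except KeyError:
            raise ValueError(f"tabulated kernel has no pmf for k={k}") from None

    def mean(self, k: int) -> float:
        p = self.pmf(k)
        return float(np.sum(np.arange(p.size) * p))

    def var(self, k: int) -> float:
        p = self.pmf(k)
        v = np.arange(p.size)
        mu = np.sum(v * p)
        return float(np.sum((v - mu) ** 2 * p))

    def max_support(self, k: int) -> int:
        p = self.pmf(k)
        return int(np.flatnonzero(p)[-1]) if np.any(p > 0) else 0

    def sample(self, k, rng):
        k = np.asarray(k, dtype=np.int64)
        out = np.zeros_like(k)
        for kv in np.unique(k):
            if kv == 0:
                continue
            p = self.pmf(int(kv))
            mask = k == kv
            out[mask] = rng.choice(p.size, size=int(mask.sum()), p=p)
        return out

    @property
    def eps_sup(self) -> float:
        return max(self.eps(k) for k in range(1, self.k_analysis + 1))

    @property
    def eps_inf(self) -> float:
        return min(self.eps(k) for k in range(1, self.k_analysis + 1))

    @property
    def delta2_sup(self) -> float:
        return max(self.var(k) for k in range(1, self.k_analysis + 1))

    @property
    def eta(self) -> float:
        return max(self.max_support(k) / k for k in range(1, self.k_analysis + 1))

    @property
    def summaries_numeric(self) -> bool:
        return True

    def to_config(self) -> dict:
        return {
            "kind": self.kind,
            "table": {str(k): {str(i): float(p) for i, p in enumerate(v) if p > 0} for k, v in self.table.items()},
        }


def _pmf_from_mapping(mapping: dict) -> np.ndarray:
    keys = {int(k): float(v) for k, v in mapping.items()}
    if any(k < 0 for k in keys):
        raise ValueError("pmf support must be non-negative integers")
    out = np.zeros(max(keys) + 1)
    for k, v in keys.items():
        out[k] = v
    return out


def kernel_from_config(cfg: dict) -> ControlKernel:
    """Build a kernel from its JSON configuration (``{"kind": ..., ...}``)."""
    kind = cfg.get("kind")
    if kind == "identity":
        return IdentityKernel()
    if kind == "binomial_thinning":
        return BinomialThinningKernel(cfg["p"])
    if kind == "random_emigration":
        return EmigrationKernel(_pmf_from_mapping(cfg["removal_pmf"]))
    if kind == "random_immigration":
        return ImmigrationKernel(_pmf_from_mapping(cfg["addition_pmf"]))
    if kind == "tabulated":
        table = {int(k): _pmf_from_mapping(v) for k, v in cfg["table"].items()}
        return TabulatedKernel(table, k_analysis=cfg.get("k_analysis"))
    raise ValueError(f"unknown control kernel kind: {kind!r}")
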