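# ctrlbranch

Simulation and exact analytics for **controlled branching processes with
infection thinning in i.i.d. random environments**.

Epidemics interact with population dynamics in two distinct ways: an
infection can remove individuals from reproduction, and the environment
(season, intervention regime, viral strain) changes the reproductive law
itself from one generation to the next. `ctrlbranch` implements a discrete
population model that couples both mechanisms with a random *control
function* (emigration, immigration, participation thinning) and provides
the tools a modeller needs to answer the basic questions: what is the exact
law of the next generation, will the population certainly die out, and how
does the properly normalized population behave in the long run?

## The model

An i.i.d. environment sequence ξ₀, ξ₁, … takes values in a finite set of
states θ, each carrying an offspring pmf {P_r(θ)}, an infection-survival
probability α(θ) ∈ (0, 1], and a control kernel Q(θ; k, ·).  Given the
current size Z_n and environment ξ_n:

    Z_{n+1} = Σ_{j=1}^{φ_n(Z_n)} X_{nj} · I_{nj}

where φ_n(Z_n) ~ Q(ξ_n; Z_n, ·) is the number of individuals participating
in reproduction, X_{nj} ~ {P_r(ξ_n)} are i.i.d. offspring counts, and
I_{nj} ~ Bernoulli(α(ξ_n)) marks escape from infection (an infected
individual leaves no offspring).  Writing m(θ) for the offspring mean,
ε(θ, k) = E[φ(k)]/k for the participation rate with sup ε(θ) and inf ε₁(θ)
over k ≥ 1, and δ²(θ, k) = Var φ(k), the package computes:

* **exact one-step transition laws** P(ξ_n; i, j) as control-kernel
  mixtures of convolution powers of the thinned offspring pmf
  (pgf 1 − α + α f_θ(s)), with explicit truncation tail tracking;
* conditional moments E(Z_{n+1}|Z_n=i) = i·m·α·ε(θ,i) and
  Var(Z_{n+1}|Z_n=i) = i·ε(θ,i)·Var(XI) + m²α²·δ²(θ,i), cross-checked
  against the exact pmfs;
* the **certain-extinction criterion** E[log(η N₀ α(ξ₀) m(ξ₀))] ≤ 0 (η a
  deterministic dominator of φ(k)/k), a nested-pgf lower-bound iteration
  μ_n for the quenched extinction probability, and Monte-Carlo extinction
  frequencies with Wilson intervals;
* **martingale diagnostics** for the normalized processes Ŵ_n = Z_n/S_n
  (supermartingale, S_n = N₀·Π m α ε) and W̄_n = Z_n/I_n (submartingale,
  I_n with ε₁), including the exact mean identity, an L² bound, the
  Doob increasing process, nondegeneracy certificates via envelope
  functions, and the r_k statistic behind L¹ convergence.

## Worked example

The built-in scenario `S3_supercritical_gw` is a single-state environment
(offspring {0: 0.2, 1: 0.2, 2: 0.6}, α = 0.8, identity control), i.e. a
classical Galton–Watson process with thinned pgf 0.36 + 0.16 s + 0.48 s²:

```python
import ctrlbranch as cb

sc = cb.get_scenario("S3_supercritical_gw")
state = sc.law.states[0]

rep = cb.extinction_criterion(sc.law, n0=1)
print("criterion:", round(rep.expectation, 5), rep.conclusion)

mu = cb.iterate_mu([state] * 400, n0=1, n=400)
print("extinction probability (pgf fixed point):", round(mu.limit_estimate, 6))

est = cb.mc_extinction_probability(sc.law, n0=1, n_max=300, reps=20_000, seed=42)
print(f"Monte-Carlo frequency: {est.frequency:.4f}  95% CI [{est.ci_low:.4f}, {est.ci_high:.4f}]")
```

prints

```
criterion: 0.11333 criterion_positive
extinction probability (pgf fixed point): 0.75
Monte-Carlo frequency: 0.7546  95% CI [0.7485, 0.7605]
```

The criterion log(1·1·0.8·1.4) = log 1.12 ≈ 0.11333 is positive, so certain
extinction cannot be concluded; the μ iteration converges to the smaller
root 3/4 of 0.48 s² − 0.84 s + 0.36 = 0 — the classical extinction
probability — and 20 000 simulated paths reproduce it within the Wilson
interval.

A command-line surface wraps the same functionality:

```
ctrlbranch scenario list
ctrlbranch transition --scenario S1_critical --size 2
ctrlbranch extinction --scenario S3_supercritical_gw --seed 7
ctrlbranch limits --scenario S5_emigration --n 50 --reps 10000 --seed 11
ctrlbranch selftest
```

Scenario JSON files (see `ctrlbranch.config`) let you define your own
environment laws; validation errors name the offending field.

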