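# Methods

## Model and assumptions

The process is a discrete-generation branching model in an i.i.d. random
environment with two thinning layers. Each generation n draws an
environment state ξ_n from a finite law; the state fixes (a) a
finite-support offspring pmf {P_r(θ)}, (b) an infection-survival
probability α(θ) ∈ (0, 1], and (c) a control kernel Q(θ; k, ·), the law of
the participation count φ(k) out of k individuals present. Given
Z_n = k and ξ_n, the next size is the sum over φ(k) participants of
independent products X·I, X the offspring count and I ~ Bernoulli(α) the
infection-escape mark. Conditional on the environment, offspring counts,
infection marks and the control are mutually independent, and (X, I)
pairs are i.i.d. across individuals within a generation.

Standing assumptions are checked per state and reported as *warnings*, not
errors: 0 < P₀ + P₁ < 1, a genuinely random control (0 < Q(θ; k, k) < 1),
and 0 < α < 1. The boundary cases are kept deliberately usable because
they are the classical reductions the test suite leans on as oracles:
identity control gives the uncontrolled process, α = 1 the uninfected one,
and a single state the classical Galton–Watson process.

Size 0 is forced absorbing (Q(θ; 0, 0) = 1 for every kernel, including
immigration): participation-rate summaries ε(θ, k) = E[φ(k)]/k are defined
over k ≥ 1 only, avoiding the 0/0 at extinction. ε(θ) and ε₁(θ) denote
the sup and inf over k ≥ 1.

## Control kernels and their summaries

Five kernel families are built in; each exposes pmf, mean, variance, and
the scalar summaries (ε-sup/inf, δ²-sup, dominating ratio η) in closed
form where the family admits one:

| kernel | ε(k) | ε / ε₁ | δ²(k) | η |
|---|---|---|---|---|
| identity | 1 | 1 / 1 | 0 | 1 |
| binomial thinning p | p | p / p | k p(1−p) (δ²-sup = ∞) | 1 |
| emigration, removal E | 1 − E[min(E,k)]/k (↑) | 1 / P(E=0) | Var (k−E)⁺ | 1 |
| immigration, addition M | 1 + E[M]/k (↓) | 1+E[M] / 1 | Var M | 1 + max M |
| tabulated | numeric | scanned over k ≤ K_analysis | numeric | numeric |

For tabulated kernels the sup/inf are finite scans over a configurable
horizon (K_analysis, default 512) and labelled as such; sup over all k is
not computable generically. η is the minimal deterministic dominator
sup_k max-support(φ(k))/k, a legitimate i.i.d. choice since the
environment is i.i.d.; it is overridable per state, and η = ∞ (possible
only for pathological tabulated kernels) disables the extinction
criterion with an explicit "inapplicable" verdict.

## Exact transition law

The textbook form of the one-step law sums over all tuples of
(offspring, indicator) pairs with a given total — exponential in the
participation count. The package instead convolves: the thinned offspring
pmf (mass 1 − α + αP₀ at 0, αP_r at r ≥ 1) is raised to the k-th
convolution power and mixed over k with kernel weights. The two forms are
identical; the enumeration survives only as a brute-force oracle in the
tests (participation ≤ 4, support ≤ 4).

All pmfs are truncated at a cap J_max (default 4096) with the lost mass
tracked as an explicit, monotone `tail_mass`; nothing is silently
renormalized (pmf drift above 1e−9 is an error, below it an explicit
renormalization). Moment cross-checks use truncation-aware tolerances
|analytic − numeric| ≤ 1e−9 + J_max · tail_mass. Multi-step quenched
propagation first mixes the kernel over the current size distribution to
get the participation-count law, then convolves the thinned offspring pmf
in once per participation unit — O(support) convolutions per generation
rather than per (size, generation) pair.

## Simulation

Two sampling modes, equal in distribution (enforced by a two-sample
chi-square test at the 10⁻³ level): *per-individual* classifies each of
the φ participants jointly by (infection outcome, offspring count) in one
multinomial draw; *compound* (default) draws survivors ~ Binomial(φ, α)
first and then one multinomial over offspring values. The ensemble engine
is generation-synchronous and vectorized across replicates, grouped by
environment state; one master seed makes the whole ensemble
bit-reproducible (reproducing a single replicate means re-running the
ensemble — the trade against per-replicate streams was made for a ~100×
speedup of the Monte-Carlo checks).

Supercritical paths grow geometrically; a population cap (default 10⁸)
freezes a path with an explicit overflow flag rather than clipping.
Analyses for which frozen paths would bias an exact identity (the mean
identity below) raise the cap to 10¹² instead, trading time for
exactness; extinction-frequency estimates keep the default cap, since a
path at 10⁸ individuals contributes zero extinction mass either way.

## Extinction analysis

*Criterion.* The annealed certain-extinction criterion evaluates
E[log(η N₀ α(ξ₀) m(ξ₀))] exactly over the finite environment law (never by
sampling). The conclusion requires a second hypothesis: strict
monotonicity of g(s) = (1 − (1−α+αf(s))^{ηN₀})/(1−s) on (0, 1), certified
numerically on a 10⁴-point grid with the s → 1 limit η N₀ α m appended —
a finite certificate, not a symbolic proof. N₀ enters the criterion
inside the logarithm; the report flags when the conclusion flips between
the given N₀ and N₀ = 1.

*μ iteration.* The lower bound for the quenched extinction probability
nests the thinned pgfs of the first n environment states, innermost
first, each raised to its dominating exponent η_t, the outermost level
carrying η₀N₀. The nested form is the defining one; a one-line
"fixed-point" rewriting of it is exact only for N₀ = 1, so the package
implements the nest (with an O(n) fast path for constant environment
sequences and an O(n²) generic path). Exponents may be non-integral; real
powers are used. Iterates are monotone nondecreasing in [0, 1]; the
stopping rule is |μ_{k+1} − μ_k| < 1e−12 or the horizon, and critical
cases that converge slowly are reported unconverged rather than
extrapolated. For a single state with identity control and N₀ = 1 the
limit is the smallest fixed point of the thinned pgf, which the tests
verify against an independent polynomial-root oracle.

*Monte Carlo.* Finite-horizon extinction frequency with a Wilson 95%
interval (scipy's binomtest), documented as an under-estimate of the true
extinction probability.

## Normalized processes

Conditional means sandwich E(Z_n | ξ⃗) between N₀·Π m α ε₁ and
N₀·Π m α ε, motivating the normalizers S_n (with ε) and I_n (with ε₁),
both computed in log space; Ŵ_n = Z_n/S_n is a nonnegative
supermartingale with one-step ratio ε(ξ_n, Z_n)/ε(ξ_n) ≤ 1, W̄_n = Z_n/I_n
a submartingale with ratio ε(ξ_n, Z_n)/ε₁(ξ_n) ≥ 1. Ratios are verified
against the exact one-step pmf within 1e−9 plus tail correction. After
extinction both processes are exactly 0 (no 0/0 ambiguity); ε₁ = 0 makes
I_n degenerate and raises an explicit error.

*Mean identity.* Iterating the one-step conditional mean gives, exactly,
E(Ŵ_{n+1}) = 1 − Σ_{k≤n} E[Ŵ_k (ε(ξ_k) − ε(ξ_k, Z_k))/ε(ξ_k)]. The
Monte-Carlo check forms the per-path statistic Ŵ_{n+1} + Σ Ŵ_k·deficit_k,
whose expectation is exactly 1, and requires agreement within 4 standard
errors. The same deficit increments define the Doob increasing process
T_n of the supermartingale, exposed per path.

*L² bound.* For single-state laws (deterministic S_i) the bound
1 + Σ m₂/(S_i α ε m²) + Σ δ²/(S_i² ε²) is evaluated exactly, including the
closed geometric limit when the growth factor m α ε exceeds 1; ensembles
confirm empirical E(Ŵ_n²) stays below it. δ²-sup = ∞ (binomial thinning)
is reported "inapplicable", subcritical growth "diverging".

*Condition series.* The sufficient-condition series for L¹/L²
convergence are evaluated exactly for any finite law, using the
independence factorization E[g(ξ_i)/S_i^p] = E[g]·E[(mαε)^{−p}]^i/N₀^p
(S_i depends only on earlier states). Verdicts use a ratio test over the
last 10 terms (< 0.999 converging, > 1.001 diverging, else inconclusive),
with one sharpening: terms bounded away from zero are reported diverging
outright, since vanishing terms are necessary for convergence. All
verdicts are finite numerical certificates and labelled as such.

*Nondegeneracy.* The envelope condition needs a nondecreasing minorant
φ_θ of k ↦ ε(θ, k) with x·φ_θ(x) convex. Such envelopes exist whenever
the ε sequence is nondecreasing but are not constructive in general; the
package ships exact closed-form envelopes for the kernel families that
admit one (identity, binomial thinning: constants; emigration:
1 − E[min(E, x)]/x, whose x-scaled version x − E[min(E, x)] is convex
because min(e, x) is concave) and a piecewise-linear interpolation
fallback for tabulated kernels, with the required properties verified
numerically on a grid. User-supplied envelopes are accepted. Partial
products of E[φ_{ξ_i}(N₀ Π_{j<i} m α ε₁)/ε(ξ_i)] are exact for
single-state laws and Monte Carlo otherwise; products stabilizing above 0
certify P(Ŵ > 0) > 0, decay toward 0 is inconclusive (the theorem is
one-directional). Deficits below 1e−12 — float resolution of 1 − φ/ε —
are treated as zero so rounding noise cannot mask convergence.

*r statistic.* r_k(θ) = k⁻¹ E|Z′ − k ε₁ m α| is computed exactly from the
one-step pmf (truncation tail above 1e−6 is an error). A probe over
k ∈ {1, 2, 4, 8, 16, 32} reports whether the sequence is nonincreasing —
the hypothesis under which the submartingale converges in L¹. Note that
for emigration-type controls with ε₁ < lim_k ε(θ, k) the sequence is
*not* eventually nonincreasing: Z′ concentrates near k m α ε(θ, k) while
the reference point is k m α ε₁, so r_k → m α (lim ε − ε₁) > 0 from
below after an initial dip (on the shipped emigration scenario:
1.536, 1.105, 1.034, 1.070, 1.126, 1.163). The L¹ hypothesis naturally
fits immigration-type controls, where ε(k) ↓ ε₁ and r_k → 0.

*Survival-set diagnostic.* Along a realized path the partial sums of
1 − ε(ξ_k, Z_k)/ε(ξ_k) are reported (they should stay bounded on paths
with Ŵ > 0). Conditioning on survival is by simple rejection of extinct
paths, which is biased at small horizons; the diagnostic is labelled as
such. The series is evaluated at the running size Z_k — the index pairing
used consistently by the one-step mean — and truncates with a flag at
extinction.

## Scenarios and problem sizes

The six built-in scenarios fix the study conditions: S1 critical
(offspring {0:.25, 1:.25, 2:.5}, α = 0.8, m α = 1), S2 subcritical
(α = 0.72, m α = 0.9), S3 supercritical single-state Galton–Watson
(m α = 1.12, extinction probability 3/4), S4 a mixed sub/supercritical
two-state law with binomial thinning 0.9, S5 strong offspring (m = 3)
with Bernoulli(1/2) emigration and N₀ = 2 (nondegenerate normalized
limit), S6 the α = 1 identity-control reduction. Every scenario carries
expected-behaviour annotations that `selftest` re-derives.

Monte-Carlo problem sizes were chosen so each check resolves its target
comfortably: 10⁵ replicates for one-step laws (TV ≈ 10⁻³ attainable,
threshold 0.01), 2×10⁴ paths at horizon 200–300 for extinction
frequencies (Wilson half-width ≈ 0.006), 10⁴ paths for the martingale
identities at n = 20 (the 4σ band is then a few percent). Exact
computations (criteria, pmfs, bounds, r_k) are deterministic and
seed-independent.

## What the generator does and does not emulate

The synthetic environments are finite-state and i.i.d., with
finite-support offspring laws — exactly the regime the analysis covers.
Passing tests therefore say nothing about stationary-ergodic or
continuous environment spaces, infinite-support offspring laws, or
convergence *rates*, all of which are out of scope. Monte-Carlo checks of
identities are consistency checks at the stated sizes, not proofs.

## Known limitations

* Annealed extinction probabilities for multi-state environments have no
  closed form; the package provides the μ lower bound and Monte-Carlo
  estimates only.
* Series verdicts and the monotonicity certificate are finite numerical
  checks; a "converged-to-finite" verdict is evidence, not proof.
* The submartingale L¹ hypothesis (nonincreasing r_k) fails for
  emigration controls whose participation rate rises with k (see above);
  the package reports this honestly rather than forcing the check.
* Configuration errors carry JSON field paths (pydantic style), not
  source line numbers.
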