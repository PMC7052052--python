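# Methods

## Scope and model structure

`mmcoal` simulates the genealogy of an n-sample from two families of
discrete Cannings models — modified Moran models and the heavy-tailed
(Schweinsberg) model — with deterministically varying population sizes of
order N, together with their limiting (time-changed) Λ-n-coalescents.
All processes are haploid, generations non-overlapping, and the sample
is taken in the present generation (r = 0, with r counting generations
into the past).  Ξ-coalescents (simultaneous-multiple-merger limits of
diploid models), random population-size processes, selection models and
parameter inference are out of scope.

## Λ-measures and rates

The measure Λ is either a point mass at ψ ∈ [0, 1] or a Beta(a, b)
density; the underlying measure is always a probability measure and a
`rate_multiplier` c₂ > 0 scales all rates uniformly (equivalent to a
linear change of time units).  Rates λ_{b,k} use the closed Beta-function
form, evaluated as differences of log-Beta functions so that block
counts of 10⁴ and population sizes of 10⁶ cannot overflow; point masses
evaluate the integrand with the convention 0⁰ = 1.  The jump-chain pmf
C(b,k)λ_{b,k}/λ_b is cached per (measure, b).

## Offspring laws

For a measure Λ, the sweepstake offspring variable U′_N is distributed
as the first merger size of the Λ-N-coalescent; its pmf is computed in
log space over {2..N} and normalized at the end (the normalizer is the
total rate λ_N), stable well beyond N = 10³.  Two exact identities are
used throughout and asserted in tests: E((U′_N)_k) = (N)_k E(X^{k−2})/λ_N,
and hence c′_N = E((U′_N)_2)/(N)_2 = 1/λ_N.  The rarefied law thins the
sweepstake draw by an independent activation event with probability
N^{−γ}λ_N (γ ∈ (1, 2)), substituting the standard Moran value U = 2
otherwise, so that c_N = N^{−γ} + (1 − P(A_N))·2/((N)_2) exactly.
Rarefaction is refused (with the smallest admissible N reported) when
N^{−γ}λ_N > 1.  The regime condition that N/λ_N stay bounded away from
zero is an asymptotic statement; it is checked heuristically on the grid
{N, 2N, 4N} and produces a warning only.  A `custom` provenance accepts
any pmf on {2..N} (e.g. two-point sweepstake models), so such variants
are configuration, not code.

## Size profiles and trajectories

A profile ν(t) (ν(0) = 1, positive and bounded on the horizon) is
realized as a backward trajectory N_r.  Exponential profiles use the
geometric recursion N_r = ⌊N(1 − ρc_N)^r⌋ — under growth (ρ > 0) sizes
shrink going back in time and at most ~Nρc_N + 1 individuals are added
per generation; the same factor (> 1) covers decline.  Other profiles
round N·ν(r·c_N) half-to-even.  Trajectories materialize at most 10⁶
generations and evaluate the recursion on demand beyond that, so
Kingman-scale horizons (c_N⁻¹ ≈ N²/2 generations) carry no memory cost.
A profile dipping below max(2, n) individuals is a hard error; clamping
caused purely by rounding, and extension beyond the requested horizon,
are warnings.  `spread_instantaneous` replaces a single-generation jump
of ⌊mN⌋ by ⌈1/√c_N⌉ consecutive generations of ≈ mN√c_N each (summing
exactly to the jump), which keeps per-generation relative increments
vanishing — the construction needed for bottlenecks that are
instantaneous on the coalescent time scale.

## Discrete engines

One Moran generation is: a fixed-size step at N_r (one multiplier with U
offspring, U − 1 non-reproducers, the rest single), then the resize.
Decline retains a uniform without-replacement subset, making the
surviving brood hypergeometric — this preserves every merger functional
Φ exactly (verified by full enumeration for N_r ≤ 8).  Growth adds A
individuals to the multiplier and d − A as single offspring of
non-reproducers, with A set by the allocation scheme: `to_multiplier`
(A = d), `to_nonreproducers` (A = 0, feasible only when d ≤ U − 1), or
`proportional` (A ~ Binomial(d, U/N_r), any overflow beyond the U − 1
non-reproducer slots forced to the multiplier, deterministically after
the draw).  A decline can degenerate the brood to U_eff ≤ 1; such a
generation simply has no multiplier and no possible multi-merger.

Genealogies are followed lineage-wise.  Because offspring order is
exchangeable, the b ≤ n lineages occupy uniformly random distinct
offspring slots, so the number landing in the multiplier's brood is
Hypergeometric(N_{r−1}, U_eff, b); those lineages merge.  No
population-sized array is materialized, and on constant-size stretches
the per-generation merger probability q(b, N) is computed once from the
offspring pmf and merger-free generations are skipped with a geometric
draw (the conditional (U, K) given a merger is then sampled directly).
A dedicated test checks that the skipping and per-generation paths give
the same coalescence-time distribution.  The explicit slot-level
operations (`fixed_step`, `resize_decline`, `resize_growth`,
`ancestry_update`) remain available and are what the diagnostics sample
from, keeping the two layers mutually checkable.

The Schweinsberg engine draws i.i.d. potential offspring with
P(X ≥ k) = k^{−α} exactly (inverse CDF: X = ⌊U^{−1/α}⌋).  This is the
simplest law satisfying the required tail asymptotics (tail constant
C = 1, mean ζ(α) > 1 for α > 1); α = 1 is supported by the sampler but
refused by moment-based operations (infinite mean).  Realized family
sizes after subsampling the pool are multivariate hypergeometric (drawn
with numpy's generator, never materializing the pool); on the
exponentially rare shortfall the missing individuals attach to
independently uniform parents, preserving exchangeability.  Several
parents can gather ≥ 2 lineages in one generation; each group is
recorded as a separate merger at the same generation.  A Chernoff bound
for the shortfall probability (minimizing u^{−(1+ε)}f(u) over u ∈ (0,1),
with the pgf f evaluated by a 10⁵-term series plus an exact tail bound)
is exposed and validated against simulation.

## Limit coalescents and the time change

The limit sampler runs the standard jump-hold construction: wait
Exp(λ_b), merge k of b blocks with probability C(b,k)λ_{b,k}/λ_b, the
subset uniform.  A time change G(t) = ∫₀ᵗ ν(s)^{−γ} ds transforms only
the clock: internal waits W ~ Exp(λ_b) are mapped through
t = G⁻¹(G(t₀) + W).  Exponential profiles use the closed forms
G(t) = (ργ)⁻¹(e^{ργt} − 1) and G⁻¹(y) = log(1 + ργy)/(ργ); other
profiles use adaptive quadrature (absolute tolerance 1e−10) and a
bracketed Brent root find (tolerance 1e−10 in t).  γ = 0 encodes the
logarithmic-c_N case, for which G is the identity regardless of the
profile — size changes then leave the limit genealogy untouched.  The
standard and time-changed samplers consume identical random draws, so
matched seeds give identical jump chains; a test asserts this.  γ is
always supplied explicitly (by the caller or the CLI): it is a property
of the pre-limit model, and only the proved pairings (2 for the classic
Moran model, α for Beta-matched Moran models, α − 1 for the heavy-tailed
model) are documented rather than inferred.

The printed Gompertz waiting-time CDF under exponential growth carries a
negative exponent, 1 − exp(−λ_b(ργ)⁻¹e^{ργt₀}(e^{ργt} − 1)); this is the
only form consistent with the general identity
P(T > t₀ + t | T₀ = t₀) = exp(−λ_b(G(t₀+t) − G(t₀))) and with a proper
CDF limit of 1.

Mutations are a Poisson process of intensity θ on branch length in the
limit trees; the discrete engines expose the matching per-generation,
per-lineage mutation probability μ_N = θ·c_N.

## Statistical verification

All Monte-Carlo estimators report binomial or empirical standard errors,
and test tolerances are expressed in SE multiples (typically 3–4),
never absolute constants; distribution comparisons use two-sample KS,
one-sample KS against closed-form CDFs, and χ² with bins of expected
count < 5 pooled into the largest-size bin, at significance 0.01 with
fixed seeds.  Pairwise-coalescence estimators Rao-Blackwellize the slot
choice — per replicate the generation is realized and a Bernoulli trial
uses the conditional pair probability Σᵢ mᵢ(mᵢ−1)/(M(M−1)) — which is
distributionally identical to picking two random individuals but
vectorizes over replicates.  The c_N ~ N^{1−α} scaling of the
heavy-tailed model is checked as a weighted log-log regression over
N ∈ {50..800} with 2×10⁵ pair replicates per size; the classic Moran
model run through the same regression recovers slope −2.

## Problem sizes

Default study conditions follow the regimes in which the constructions
are stated: sample sizes n ≤ ~20, reference sizes N between 50 and 10³
for genealogy-level tests (2×10³ pair replicates for KS at N = 300,
500 replicates for jump-chain χ² at N = 80, 5×10³ replicates for the
Gompertz law), and N up to 10⁵–10⁶ only for deterministic trajectory
and pmf checks.  These sizes make every distributional test reproducible
on a single CPU in minutes while keeping MC standard errors well below
the effects being tested.

## Known limitations

* Convergence to the limit is O(N^{−something}) slow in regimes where
  c_N retains a sizeable Kingman remainder.  For the rarefied Dirac(0.5)
  model with γ = 1.5 at N = 80, the remainder 2/((N)_2) is ~18% of c_N
  per pair and scales with the number of pairs, so roughly half of all
  first mergers in an n = 6 sample are binary standard-Moran events and
  the first-merger size law measurably differs from the limit jump chain
  (the suite contains both this comparison and a test validating the
  engine against the exact finite-N law).  Conclusions about real data
  at moderate N should use the finite-N law, not the limit.
* The allocation schemes implemented are the three named ones; the
  theory permits any allocation that preserves the modified-Moran
  structure, and no attempt is made to enumerate others.
* Asymptotic hypotheses (regime conditions, vanishing relative
  increments) can only be spot-checked at finite N; they surface as
  warnings, not errors.
* Tabulated profiles extrapolate as constant beyond their range (with a
  warning) when a genealogy outlives the horizon.
* The synthetic models are exchangeable and neutral by construction;
  none of the tests say anything about selection, population structure,
  or overlapping generations.
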