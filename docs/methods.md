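# Methods

## Model

One dataset holds gas-exchange observations from a single growing
environment; environments are fitted separately rather than pooled, so an
environment contrast is a contrast between independent posteriors.

For observation *i* on plant *p(i)* of genotype *g(p)*:

* `A_N[i] ~ Normal(µ[i], sd = 1/√τ)` — Gaussian measurement noise with one
  shared observation precision τ per fitted dataset.
* `µ[i]` is the non-rectangular hyperbola evaluated at `PAR[i]` with plant
  *p(i)*'s parameters `(A_max, α, R_d, θ)`. The hyperbola is the smaller
  root of `θz² − (αI + A_max)z + αI·A_max = 0` minus `R_d`; the smaller
  root is the physical branch (the larger one exceeds `A_max`). Its
  discriminant is provably non-negative for `0 < θ ≤ 1`; round-off
  negatives above −1e−10 are clamped to zero and anything more negative
  raises, since it signals parameters outside the model's domain. Below
  θ = 1e−6 the closed-form θ→0 limit `αI·A_max/(αI + A_max) − R_d` is used
  to avoid the 0/0 cancellation in the quadratic formula.
* Plant parameters are truncated-normal around their genotype's mean with
  per-parameter precision `τ.Parameter` shared across genotypes; genotype
  means are truncated-normal around the prior centre. Two stochastic
  levels (plant within genotype) — the environment factor is handled by
  separate fits, not a third level.

Truncation supports: `A_max ∈ (0, 100]`, `α ∈ (0, 0.125]` (the theoretical
quantum-yield ceiling), `R_d ∈ [0, 10]`, `θ ∈ (0, 1]`, all in the units of
the README. Prior centres default to literature-typical rice values
(25, 0.05, 1.5, 0.8) with sd = 2 × centre — a deliberately diffuse
"±200%" spread — and all precisions get Gamma(shape 0.01, rate 0.01).
Because the source tables for the prior centres are not distributed with
the package, the centres are plain defaults; pass a custom `PriorSpec` to
use your own.

## Sampler

Adaptive Metropolis-within-Gibbs, one compiled (numba) routine per chain:

* plant-level parameters: scalar Gaussian random-walk per (plant,
  parameter); plants are conditionally independent given the genotype
  level, so one parameter slot is proposed for every plant at once and
  accepted plant-by-plant;
* genotype means: scalar Metropolis, plus a joint *shift* move that
  translates a genotype mean together with all its plants' values. The
  shift move is what makes the hierarchy mix: without it the mean can only
  random-walk against its plants' conditional prior;
* genotype precisions: Metropolis on log τ. The truncated-normal
  normalising constants depend on τ, so the gamma conditional is *not*
  conjugate and a Gibbs draw would be wrong here;
* observation precision: exact conjugate gamma Gibbs draw.

Proposal scales adapt in batches of 50 iterations toward a 30% acceptance
target during burn-in (multiplicative updates shrinking as 1/√batch) and
are frozen afterwards, so retained draws come from a fixed, valid kernel.
A chain whose post-adaptation acceptance rate leaves (0.05, 0.95) raises —
that signals broken tuning, not a usable posterior. Chains start from
overdispersed points (genotype means jittered ±25% of the prior width);
chain seeds derive from one master seed via `SeedSequence`, so every fit is
reproducible bit-for-bit.

The retained-draw convention matches the "10,000 iterations, thinned every
10th, 10,000 values per chain" protocol: `n_iter` counts *retained* draws,
so a default fit runs `n_adapt + 10 × 10,000` raw iterations per chain and
pools 30,000 draws from 3 chains. Scaled-down configurations used in the
test suite (e.g. 3 × 1,200 retained, thin 4) were chosen as the smallest
runs whose PSRF stays near 1 on the study-sized problems.

## Verification strategy

* **Grid oracle.** On a reduced model — one plant, α and θ fixed, known
  observation sd, free `(A_max, R_d)` — the posterior is computed by brute
  force on a 401×401 grid with none of the sampler machinery, and the
  sampler (restricted to the same two coordinates but running the
  production update kernel) must reproduce its marginal means within 2%
  and sds within 10%. This is the direct correctness check on the MCMC.
* **Recovery.** The generator returns its ground truth, so credible
  intervals can be scored against the exact generating values; across 20
  replications of the full field design the 95% intervals for
  genotype-level `A_max` cover truth ≥ 80% of the time.
* **Procedure error rates.** The subsample ANOVA's type-I rate under
  identical posteriors and its power under a 3-posterior-sd shift are
  measured with 200 replications of real (small) MCMC fits.

## What the generator emulates — and what it does not

The generator reproduces the statistical structure the model assumes:
genotype means drawn around global hyper-means (defaults `A_max` 25±3,
`α` 0.05±0.005, `R_d` 1.5±0.3, `θ` 0.8±0.05 — within the ranges rice
field studies report), plant parameters around genotype means with half
that spread, Gaussian observation noise (default sd 1.0 µmol CO₂ m⁻² s⁻¹,
typical gas-exchange scatter), and the three measurement geometries: the
7×5×3 ambient-light field survey over PAR 1–2400 (ambient light proxied by
`sin(π·u)` of a uniform time-of-day draw with ±10% sky jitter), and the
two fixed ladders (2000…50 chamber, 1400…0 greenhouse). Truncated-normal
draws use plain rejection (exact; fails loudly after 1000 tries if the
hyper-parameters fight the support).

It does *not* emulate instrument drift, leaf-temperature physics,
temperature/VPD covariate effects on the curve, non-Gaussian outliers, or
model misspecification of any kind. Passing tests therefore demonstrate
that the machinery is correct *when the model is true*; they say nothing
about robustness to the ways real LI-6400 data violate the model.

## Known limitations

* With daytime-only or high-light-heavy designs, `θ`, `R_d` and `α` are
  weakly identified and trade off against `A_max`. Under the diffuse
  default priors this inflates `A_max` posteriors by roughly 1–3
  µmol CO₂ m⁻² s⁻¹ in study-sized simulations (3–5 plants per genotype)
  and pushes 95% credible-interval coverage of genotype `A_max` toward
  ~0.7–0.85 rather than the nominal 0.95. This is a property of the model
  plus priors, not of the sampler (the grid oracle rules the sampler out);
  no reparameterisation is applied. Tighter, genuinely informative priors
  on θ and `R_d` — or designs with true dark and low-light measurements —
  shrink it.
* The ANOVA/Tukey comparison treats posterior draws as data points. That
  is statistically unorthodox (draws are not independent observations of
  anything); it is reproduced deliberately as the procedure this package
  implements, the 50-draw subsample caps its anti-conservatism, and every
  `ComparisonResult` carries the caveat in its metadata. Comparisons
  across *differently designed* measurements can flag parameters whose
  *identifiability* differs between designs even when the underlying
  truth is identical — a method effect, not a plant effect.
* One observation precision τ per fitted dataset; heteroscedastic noise
  across the light range is not modelled.
* Empirical type-7 quantiles for all credible bounds; at 30,000 draws the
  choice of quantile rule is negligible.
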