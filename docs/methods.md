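# Methods

`sadpower` asks a single statistical question: given one species abundance
sample — a list of per-species counts `(n_1, …, n_S)` summing to a community
size `J` — how likely is a maximum-likelihood test of Hubbell's standard
neutral model (SNM) to detect that the data were in fact produced by a
*non-neutral* community process?  The package contains the three pieces that
question needs: simulators for non-neutral community models, an exact
likelihood-based test of the neutral null, and the power machinery that
couples them.  This note records the models, the numerical choices, and what
the defaults do and do not represent.

## Community models

All local communities hold exactly `J` individuals (strict zero-sum
dynamics); a fraction `m` of recruits are immigrants drawn from a static
metacommunity with relative abundances `P_i`.

**Metacommunities.**  `LOGS` draws `S_T` relative abundances whose species
frequency density is the Ewens/continuum log-series form
`f_M(x) = θ x⁻¹ (1−x)^{θ−1}` — sampled by GEM(θ) stick-breaking, truncated at
`S_T` and renormalized.  The truncation leaves expected unassigned mass
`(θ/(θ+1))^{S_T}`; at the default `S_T = 2000` this is below 10⁻¹⁶ for every
θ used here, i.e. effectively infinite.  `EVEN` has `S_T` species at exactly
`1/S_T`; its `S_T → ∞` limit is represented symbolically — every immigrant
founds a species never seen locally, so immigration acts as speciation.  By
default a fresh LOGS metacommunity is drawn for every replicate data set
(one fixed draw is available via `share_metacommunity`); the chosen mode is
recorded in sample metadata.

**HL** (sequential, Moran-type): the next death is of species `i` with
probability ∝ `[(1−γ) + γ n_i/J]·(n_i/J)`; the recruit is species `i` with
probability ∝ `(1−m) n_i/J + m P_i`, evaluated on post-death abundances, so
the recruit is an immigrant with probability `m/(m + (1−m)(J−1)/J)` and
otherwise copies a uniformly chosen survivor.  One time step is `J`
elemental updates.  `γ ∈ [0,1]` measures excess intra- over inter-specific
mortality; `γ = 0` is exactly neutral.  A closed-form mapping from
stochastic Lotka-Volterra rates `(r₊, r₋, K′, α, μ)` onto `(γ, m)` is
provided (`hl_params_from_rates`), excluding strongly mutualistic `α`.

**PC** (synchronous, Wright-Fisher-type): propagule fractions follow a
Ricker penalty on fecundity, `L_i ∝ n_i e^{−c n_i/J}`; recruit probabilities
are `R_i = m P_i + (1−m) L_i` and the next generation is one
`multinomial(J, R)` draw.  `c = J(a−b) ≥ 0` is the intra-minus-inter
density-dependence difference.

**IF** (synchronous): species carry intrinsic fitnesses `f_i`, drawn once
per realisation i.i.d. from a Gamma distribution with shape `1/k` (mean 1,
so `√k` is the fitness coefficient of variation), and `L_i ∝ f_i n_i`.
Draws use the log-space identity `G_a = G_{a+1} U^{1/a}` because direct
Gamma sampling underflows to all-zero fitnesses for `k ≳ 10³`, which would
silently neutralize the dynamics; `k = ∞` is implemented exactly as a
one-hot fitness vector.  In the `k → ∞` EVEN limit the equilibrium
composition has the closed form: each individual is the dominant species
with probability `1 − m(1 − 1/S_T)`, each other species with probability
`m/S_T`; `if_kinf_even_sample` draws from this law directly.

**PC mean-map stability.**  For large `J` and vanishing `m` the PC model
reduces to the deterministic map `r_i' = r_i e^{−c r_i}/Σ_k r_k e^{−c r_k}`.
Linearizing at the uniform fixed point `r* = 1/S_T` gives the eigenvalue
`1 − c r*` (multiplicity `S_T − 1`) on the zero-sum subspace, so stability
is lost through a flip bifurcation exactly where the scaled competition
strength `c·r* = c/S_T` reaches 2 — the classic Ricker period-doubling
threshold, equivalently `c < 2 S_T` for stability.  The package locates
this boundary numerically (power iteration on a zero-sum perturbation,
bisected to 10⁻⁴) and warns when a PC run is configured beyond it.

## Equilibration

Communities are initialized with `J` i.i.d. metacommunity draws — unbiased
with respect to the local dynamics and already exact at `m = 1`.  Burn-in is
detected automatically: richness and Shannon index are recorded on a
geometric checkpoint schedule (growth 1.08) and equilibrium is declared at
the first time `T` where a trailing window of 12 checkpoints shows no
significant mean shift between its halves (Welch test at 5%); the run then
continues to `10·T` total steps.  Two deliberate choices here: the window's
time-span ratio `1.08¹¹ ≈ 2.3` bounds how far past the end of a transient
detection can lag, and a *mean-shift* test is used rather than a rank slope
statistic because sparse discrete series (richness at `m ~ 10⁻⁴` is mostly
constant with rare immigration spikes) read to rank tests as strong trends.
A configurable step cap (default 2·10⁵) turns non-convergence into an
explicit error carrying the recorded series.

`m = 1` equilibria are a technical corner: for the synchronous models the
stationary configuration is exactly `multinomial(J, P)`; for sequential HL
with `γ > 0` survivorship is species-dependent and the identity is only
approximate, so exactness tests assert it for PC/IF only.

## Exact neutral likelihood

The probability of a sample `D` under the SNM is the Etienne sampling
formula with `I = m(J−1)/(1−m)`:

    P(D|θ,m) = J!/(∏ n_i ∏ Φ_j!) · θ^S/(I)_J · Σ_{A=S}^{J} K(D,A) I^A/(θ)_A,

where `K(D,A)` convolves per-species coefficient arrays
`k_i(a) = s̄(n_i,a)(a−1)!/(n_i−1)!` built from unsigned Stirling numbers of
the first kind.  Numerics, which are the delicate part:

* Stirling rows are generated by the standard recurrence in log space, with
  every 64th raw row checkpointed so a new abundance value costs at most 64
  recurrence steps.
* The coefficient convolution spans hundreds of orders of magnitude but is a
  sum of *positive* terms, so it is evaluated chunk-wise in linear space:
  each chunk is rescaled by its maximum (chunk log-range ≤ 340, keeping all
  cross-products inside double range), multiplied with `np.convolve`, and
  merged back in log space.  Positivity makes every output coefficient
  accurate to ~10⁻¹³ relative regardless of scale; a property test checks
  the segmented product against plain log-space convolution.
* `K(D,·)` depends only on the abundance multiset and is cached on the
  sample; the `A`-sum is evaluated by streaming log-sum-exp over a window
  within 46 nats of the peak (the summand is strictly log-concave in `A`,
  checked empirically across regimes), making each likelihood evaluation
  O(window) after the one-off `K` construction.
* `m = 1` is handled as the Ewens limit; `J = 1` has probability 1.

Exactness is verified against brute-force enumeration (all abundance
configurations at `J ≤ 6` sum to probability 1 within 10⁻¹⁰ in log space)
and against the urn sampler by χ².

**Maximization** is over `(log θ, logit m)`: a 5×5 log-spaced grid of starts
(θ ∈ [1, J], m ∈ [10⁻⁴, 0.99]) is scored, then a compact Nelder-Mead
(f-tolerance 10⁻⁶) refines the best start plus the best start of any
distant, competitive basin — the surface can be bimodal, but a basin more
than 100 nats down at grid resolution never wins.  Boundary optima
(monodominant samples drive `m̂` or `θ̂` to tiny values) are flagged.
Spot-checks against a 9×9-grid, four-refinement intensive fit put the
residual under-optimization at ~10⁻⁵ nats in typical regimes; rare
strongly multimodal surfaces can retain errors of order one nat, which
enters the bootstrap comparison as symmetric noise on both the test and
null statistics rather than as bias.

**Urn sampler.**  Individual `j` is a new immigrant ancestor with
probability `I/(I+j−1)`, else copies an earlier individual; the `a`-th
ancestor founds a species with probability `θ/(θ+a−1)`, else copies an
earlier ancestor.  The scheme is exchangeable and consistent in `J` at
fixed `I`, which yields the subsampling property tested at small `J`: a
hypergeometric subsample of size `J′` matches a direct draw with `m′` such
that `I` is unchanged.

## The neutrality test and its calibration

The test statistic is the maximized log-likelihood.  For a sample: fit
`(θ̂, m̂)`; draw `u` urn replicates at the fitted values (default
`u = 1000`; each replicate on its own spawned RNG stream, so results are
independent of how replicates are distributed over workers); fit each by
the identical procedure; the p-value is the fraction of null maximized
log-likelihoods *below* the sample's (ties count ½); reject when
`p < α = 0.05`.  The direction matters: data that fit the neutral family
poorly sit in the lower tail of the null maximized-likelihood
distribution.

The maximized likelihood is not a pivotal statistic, so this plug-in
parametric bootstrap is somewhat conservative: under null data at
`(θ=50, m=0.1, J=200)` the p-value distribution is shifted high (median
≈ 0.6) while the rejection rate at `α = 0.05` stays at or below nominal
and calibrates within its Jeffreys interval.  The tests assert exactly
those two properties rather than strict p-value uniformity.

## Power estimation

Power = fraction of simulated alternative-model data sets the test rejects,
with equal-tailed Jeffreys `Beta(x+½, n−x+½)` 95% intervals (endpoints
pinned to 0/1 at `x = 0`/`x = n`).  The full-scale profile is 400 data sets ×
`u = 1000`; a reduced fast profile (100 × 200) drives the scaled-down checks.
A declarative sweep driver writes one TSV row per grid cell and skips
completed cells on restart; every cell derives its seed from the root seed
and its own parameters, so interrupted and reordered runs agree.

One equivalence subtlety is load-bearing for the neutral-limit checks: the
urn/Etienne likelihood describes the *sequential* (Moran-type) community,
while PC/IF are synchronous Wright-Fisher updates with twice the
per-generation drift.  HL(γ=0) therefore reproduces urn samples at
identical `(θ, m, J)`, but PC(c=0) matches the urn only at the
diffusion-matched immigration intensity `I_eff = 2Jm/(1−m)²` — the package's
neutral-equivalence tests use exactly that correspondence.  The hypothesis
test itself is unaffected (it fits `θ` and `m` freely), which is why the
type-I calibration sits at the nominal level either way.

## Matching empirical summary statistics

`fit_to_targets` finds `(m, diversity)` so that Monte-Carlo mean richness
and Shannon index of equilibrium samples at the empirical `J` match a
target triple (the packaged table carries the Barro Colorado, Pasoh and
Lambir values).  At each candidate diversity, `m` is solved by bisection
using the monotone rise of `E[H]` with `m`; an outer log-grid scan over
diversity records every sign change of the richness residual (0, 1 or 2
solutions) and refines each by bisection.  All expectations use common
random numbers (default 50 replicates per evaluation; tolerances 0.5
species and 0.01 nats) so the search sees a smooth objective.  For the EVEN
family, when richness still falls short at the largest finite `S_T`, the
`S_T = ∞` boundary solution is reported using the immigration-as-speciation
generator, with `m` solved against the Shannon target and the richness
residual disclosed.  A spent budget yields an explicit report carrying the
achievable `(S, H)` envelope, distinguishing "always above" from "always
below" the target.

## Problem sizes and limitations

The test suite and the acceptance script run the full pipeline at reduced
scale — `J` from 200 to 5000, 100–200 data sets per condition, `u` of
40–200 — chosen so every check completes on a single CPU while the Monte
Carlo error stays far below each assertion's tolerance; the full-scale
profile (`J ≈ 2·10⁴–3·10⁴`, 400 × 1000) runs through the same sweep driver
unchanged.

What the synthetic generators do not emulate: spatial structure (a focal
tree interacts with neighbours, not with community-mean densities — under
clumping the effective `γ` and `c` would depend on `J`), trophic or
mutualistic interactions, temporally fluctuating fitness, and observation
error in real censuses.  Passing tests therefore certify the statistical
machinery under the stated model family, not that any real forest is
neutral.  Likelihoods for multiple simultaneous samples or spatially
explicit neutral models are out of scope, as are the PC model's limit
cycle/chaos regimes beyond locating their onset.
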