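# Methods

This note records the model, the estimation machinery, and the design
choices behind `gridpop`, at the level of detail a user needs to judge what
the package's tests do and do not demonstrate.

## Process model

The landscape is a lattice of square cells (default side 2 km) with queen
(8-cell) adjacency. Inter-cell distances `DIST` are expressed in grid-cell
units — 1 for rook neighbours, √2 for diagonals, 0 for self — and converted
to km by the cell side where physical distances are reported. Each cell
carries a habitat area `A_i` (km²), z-scored covariates BLF (broad-leaf
forest area), EDGE (forest-edge length) and FRT (total forest area), a
binary river indicator RIV, a management-unit label, and an indicator of
initial occupancy. Standardization uses the population standard deviation;
the (mean, sd) pairs are stored so the transform inverts.

Within a year, growth → hunting → dispersal:

* **Growth.** `N_h[i] ~ Poisson(r_i N_r[i])`, `log r_i = α0 + α1 BLF_i +
  α2 EDGE_i`, with the biological cap `max_i r_i < 1.5` (one calf per female
  per year) enforced through the prior.
* **Hunting.** Exact subtraction of the per-cell harvest; a harvest
  exceeding a cell's abundance is an infeasibility, signalled rather than
  clipped.
* **Dispersal.** Row `i` of the annual kernel `M = (M^Δ)^16` gives the
  destination distribution for each of `N_d[i]` individuals; counts move by
  a multinomial draw, so the yearly total is conserved exactly and
  colonization of new cells is integer-stochastic.

The short-term kernel is the row softmax of `h_ij = β0 DIST_ij + β1 FRT_j +
β2 RIV_j` over the destination set {i} ∪ n_i; rows at the domain edge
renormalize over in-domain destinations, a discrete reflective boundary.
Indexing the normalizing sum over sources rather than destinations does
not define a stochastic matrix; normalizing over destinations is the only
convention that yields a row-stochastic matrix and a destination
probability vector for the multinomial, so that is what is implemented. The matrix
power is computed by binary exponentiation (4 squarings for 16 steps),
verified against step-by-step multiplication to 1e-10; rows are
renormalized afterwards to absorb floating-point drift.

**Initial state.** The first-year field follows an auto-model: each cell is
Poisson with mean `A_i Σ_{j∈n_i} N_j / Σ_{j∈n_i} A_j`, and cells with no
evidence of initial occupancy are pinned at zero. The cyclic specification
does not define a joint density, so the package treats it two ways: a
fixed-scan Gibbs sampler (`initial_state_sample`) generates fields, and the
pseudo-likelihood of full conditionals (`initial_state_logpseudodensity`)
scores them; cells with empty neighbour sets contribute no term (their
conditional is undefined), and mask-pinned cells contribute none because
they are deterministic. Both are stated surrogates for a model the source
leaves unspecified.

## Observation models

* **Pellet counts.** `F ~ NegBin(shape θ, rate θA/(γN))`, i.e. mean `γN/A`
  and variance `mean + mean²/θ`: γ is pellets per unit deer density
  (reference value 36.38, "≈36 pellets correspond to one deer"), and the
  reference θ = 0.368 makes counts extremely overdispersed — a fact that
  dominates much of the algorithm design below. `N = 0` degenerates to a
  point mass at `F = 0` (the NB limit as the mean vanishes).
* **Block counts.** `B ~ Poisson(A^B N / A)` for a surveyed sub-area
  `A^B ∈ (0, A]`.
* **Hunting records.** Unit totals `H^u` are conditioned on, never
  modelled; their latent allocation to cells is `Multinomial(H^u; p ∝ N_h)`
  within the unit (constant within-unit hunting rate). Draws violating
  `N_h ≥ H` zero the particle's weight rather than being redrawn, which
  preserves the model's support restriction.

## Particle filter

A bootstrap filter with systematic resampling at ESS < P/2 estimates the
marginal likelihood for pseudo-marginal MCMC. Its non-standard part is the
initialization, which samples first-year states directly from per-cell
filtered distributions:

1. A **pilot field** λ̃ is built from the data alone: block densities scaled
   to habitat area, pellet counts inverted through a *fixed* reference
   pellets-per-density constant (50; using the current γ here would make
   the initial prior depend on ψ and corrupt the pseudo-marginal target),
   nearest-neighbour interpolation within the unmasked region, a floor of
   0.1, and a top-up in units whose first-year hunting records exceed the
   pilot mass (records bound abundance from below; the default allowance
   is 12× the record, i.e. an assumed harvest rate of order 10%).
2. Cells are visited in a fixed scan. Cell i's **initial prior** is a
   negative binomial with dispersion κ = 1 (geometric tail) and mean
   `μ_i = (1−b)·λ̃_i + b·(auto-model conditional mean over already-sampled
   neighbours)`, b = 0.5 — a proper joint distribution that carries the
   initial range's spatial autocorrelation. The heavy tail matters: with
   θ ≈ 0.4 a pellet count is routinely a small fraction of its mean, so any
   moment-based pilot under-pitches true abundance, and a Poisson prior
   would crush the data's ability to pull the filtered conditional upward.
3. Each cell is sampled from `q(N_i) ∝ prior(N_i)·L_obs(N_i)` truncated to
   `[0, N_max]` (N_max = max(50, 5μ), extended until the prior tail mass is
   below 1e-6), where L_obs is the product of the cell's first-year pellet
   and block likelihoods. The particle's importance weight is the product
   of per-cell predictive normalizers `Σ_k prior(k)·L_obs(k)`, so the
   first-year data enter the likelihood estimate exactly once.

This initialization keeps the first-year effective sample size near P; the
naive alternative (sample the prior blindly, weight by the data) collapses
to an ESS of ~1 on fields with tens of occupied cells, and the test suite
demonstrates that contrast directly. Subsequent years use the process model
as proposal; pellet and block log-likelihoods accumulate into the weights,
hunting infeasibilities zero them, and a year in which every particle dies
makes the whole estimate −inf (a parameter value outside the data's
support). On an enumerable single-cell model the filter's estimates are
verified unbiased against an exact dynamic-programming likelihood.

## Sampler

Pseudo-marginal Metropolis–Hastings over the 8-vector ψ: the particle
filter's estimate is computed fresh for every proposal and *carried
unchanged* for the current state. Proposals follow a differential-evolution
multi-chain scheme with per-dimension crossover: a random subset of
parameters (crossover fraction drawn from {1/3, 2/3, 1}) jumps by
`g·(x_a − x_b)` using two other chains' states, `g = 2.38/√(2d′)` jittered
by U(0.5, 1), with a 10% chance of a unit-scale jump. The crossover is not
cosmetic: with populations as small as 8 chains, full-space difference
jumps couple all parameters through one shared scalar and visibly distort
the stationary marginals of box-constrained parameters (the test suite
checks the sampler against a deterministic grid posterior and against
prior recovery on an empty dataset; the full-space variant fails both, the
crossover variant passes). An adaptive burn-in stage runs the same kernel
and is discarded; retained iterations are thinned (default every 50th).
With fewer than 4 chains the sampler falls back to a fixed-scale random
walk.

Priors (hyper-values are package choices, exposed in configuration):
N(0, 10) on α0, α1, α2, β1, β2; U(−10, 0) on β0; U(0, 200) on γ; U(0, 10)
on θ; plus the hard growth cap evaluated over all landscape cells. Chain
starts are prior draws where feasible; because a persisting, spreading,
harvested population has measure ≈ 0 under blind prior draws, later
initialization attempts sample an ecologically plausible window (growth
below the cap, moderate distance decay, log-uniform observation scales)
and finally jitter already-initialized chains. Starting points do not
affect the stationary distribution.

Defaults are sized for production analyses — 8 chains, 10,000 retained
iterations, thin 50, 2,000 particles — and every stochastic element flows from one
master seed through spawned generator streams.

## Diagnostics

`gelman_rubin` is the classic (non-split) potential scale reduction factor;
`hpd_interval` the shortest interval containing ⌈mass·n⌉ sorted draws;
`summarize` combines medians, 95% (and optionally 50%) HPD intervals and
R̂. The posterior predictive check must work without retained latent
states (pseudo-marginal MCMC marginalizes them), so for each retained draw
ψ it samples one latent trajectory *conditioned on the observed data* by a
particle-filter genealogy draw (yearly resampling with recorded ancestry,
one lineage picked at the final year), computes expected counts
`E[y|ψ, states]` at the observed design points, and pools pellet and block
counts into one Freeman–Tukey statistic `T = Σ(√y − √E)²` for the observed
counts and for replicate counts drawn from the observation models at the
same states; the Bayesian p is the fraction of draws with `T_rep ≥ T_obs`.
An earlier variant that simulated *fresh* states per draw and compared the
observed data against them is mis-calibrated by construction (the replicate
is always better matched to its own generating states, driving p to 0) and
was replaced; the calibration test in the acceptance suite verifies the
conditional-state version lands centrally on well-specified data.
`demographic_maps`
reports per-cell posterior medians of `r_i` and the staying preference
`h_ii = β1 FRT_i + β2 RIV_i`.

## Synthetic data

The generator emulates the study system's statistical structure at desk
scale: Gaussian-filtered white-noise covariates (correlation length ≈ 3
cells) standardized over cells; one or two contiguous river lines; ~3×3
contiguous management units; a contiguous initial range grown to ~15% of
cells; pellet surveys at 14.3% of cell-years; block stations in 2 units
with sub-areas U(0.95, 2.21) km²; and a Binomial(unit abundance, 0.1)
hunting policy — a stand-in, since real records are conditioned on, with
infeasible allocation draws redrawn during generation so emitted records
are always consistent. The initial field seeds the occupied region at
density 15 per cell and applies one Gibbs sweep: the auto-model loses
roughly half its mass per sweep at desk scale (edge cells average in empty
neighbours), and a single sweep imposes the neighbour autocorrelation while
leaving a population of realistic size (~150 animals, in line with the
study's initial density per occupied cell).

What the generator does **not** emulate: real geography, covariate maps
extracted from vegetation data, observer effects or pellet decay,
year-to-year survey design changes, and density dependence. Passing
recovery tests on these data therefore shows the estimation machinery is
self-consistent under the model's own assumptions — not that the model is
correct for any particular real landscape.

## Test problem sizes

The scientific acceptance tests run at sizes chosen for a single CPU:
parameter recovery uses an 8×8 lattice, 6 years, 3 repetitions, 6 chains ×
370 iterations at 500 particles (a few minutes each), passing when ≥7 of 8
parameters are covered by 95% HPD intervals in ≥2 of 3 repetitions;
filter-vs-exact comparisons use 200 seeds on a single-cell, 3-year model;
prior recovery uses 10,000 thinned draws on a one-cell landscape; the
posterior-predictive calibration uses 5 repetitions of a 6×6, 4-year fit.
Production analyses should scale all of these up (the configuration
objects expose every knob).

## Known limitations

* The initial-state auto-model is a surrogate; its Gibbs sampler is not a
  draw from a well-defined joint, and the filter's sequential
  autoregressive initial prior is a second, slightly different surrogate.
  Both are documented choices, not derived facts.
* The pilot's hunting-record allowance (12×) encodes an assumed plausible
  harvest-rate scale; datasets from populations harvested at far lower
  rates would warrant raising it.
* Pseudo-marginal chains are sticky when the filter's log-likelihood noise
  exceeds ~2 (small P on large landscapes); the per-year ESS trace logged
  at INFO level is the first thing to inspect.
* No density-dependent growth or dispersal; no auxiliary or look-ahead
  particle filters; no Rao-Blackwellization beyond the initialization.
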