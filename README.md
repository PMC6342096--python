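# gridpop

Spatially explicit state-space matrix models of wildlife range expansion,
fitted by particle MCMC.

`gridpop` is for ecologists who want to estimate how environmental
covariates drive both **population growth** and **directional dispersal**
(advection) from sparse, noisy abundance-proxy surveys — the situation of
the Japanese sika deer (*Cervus nippon*) expanding across a fragmented
2×2-km landscape grid under active harvest management, where pellet-count,
block-count and hunting-record data each see only a sliver of the process.

## The model

Latent abundances `N_r[i,t]` on a lattice of cells pass through an annual
cycle of three demographic processes:

```
growth:     N_h[i,t] ~ Poisson(r_i · N_r[i,t]),   log r_i = α0 + α1·BLF_i + α2·EDGE_i,  r_i < 1.5
hunting:    N_d[i,t] = N_h[i,t] − H[i,t]           (exact removal, N_h ≥ H)
dispersal:  flows from i ~ Multinomial(N_d[i,t]; row i of M),  N_r[·,t+1] = column sums
```

The annual dispersal matrix is a power of a short-term movement kernel,
`M = (M^Δ)^(1/Δt)` with `Δt = 1/16` year (22.8 days): in one short step an
animal stays or moves to a queen-adjacent cell with softmax probabilities
built from `h_ij = β0·DIST_ij + β1·FRT_j + β2·RIV_j` (β0 < 0: distance
decay; forest and river terms make permeability directional). Multinomial
dispersal keeps integer stochasticity — range expansion into a new cell is
a chance event, as it is in nature.

Three observation models tie the latent field to data: overdispersed
negative-binomial pellet counts with mean `γ·N_r/A` (γ pellets per unit
deer density, dispersion θ), Poisson block counts over a surveyed sub-area,
and multinomial allocation of unit-level hunting totals. The eight free
parameters ψ = (α0, α1, α2, β0, β1, β2, γ, θ) are estimated by
**pseudo-marginal MCMC**: a bootstrap particle filter supplies unbiased
marginal-likelihood estimates, with first-year states drawn directly from
per-cell filtered distributions (the trick that keeps the filter alive in a
state space with hundreds of cells), and a differential-evolution
multi-chain sampler with per-dimension crossover explores ψ.

## Worked example

```python
import gridpop as gp

land = gp.build_lattice(35, 35, cell_side=2.0)      # homogeneous landscape
kernel = gp.build_kernel(land, gp.default_psi().movement())
print(gp.displacement_stats(kernel, land, origin=17 * 35 + 17))
```

prints

```
{'mean_km': 5.607627690620507, 'rms_km': 6.3538866158598415}
```

— with the reference distance coefficient β0 = −1.852 an animal's annual
root-mean-square displacement on a homogeneous landscape is ≈ 6.4 km; the
staying probability per 22.8-day step is about 0.52 per neighbourhood
softmax, and at the reference intercept α0 = 0.332 the zero-covariate
growth rate is exp(0.332) ≈ 1.39, just under the single-calf biological cap
of 1.5.

The `examples/` directory holds one short script per capability —
kernel construction, range-expansion simulation, particle-filter
likelihoods, and a full fit with diagnostics:

```bash
python examples/02_simulate_range_expansion.py
```

```
year  total  occupied-cells
   0    160         21
   ...
   8   1032        142
pellet records :  189 (14.6% of cell-years)
```

A thin command-line interface wraps the same library calls for shell use
(`gridpop simulate|fit|diagnose|recover --config cfg.yaml`); every run
writes a provenance record with the config hash and seeds.

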