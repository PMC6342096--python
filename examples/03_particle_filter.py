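"""Estimate the marginal likelihood of survey data with the particle filter.

The filter initializes first-year abundances from per-cell filtered
proposals (data-pilot × first-year likelihood, spatially smoothed through
already-sampled neighbours) and then runs the demographic model as a
bootstrap proposal, weighting by the observation models.  The log of the
averaged weights is an unbiased estimate of the marginal likelihood — the
quantity pseudo-marginal MCMC needs.
"""

import numpy as np

import gridpop as gp

land = gp.make_landscape(8, 8, seed=11)
psi = gp.default_psi()
_, data = gp.simulate_dataset(land, psi, years=6, seed=111)

P = 500
for label, candidate in [
    ("truth", psi),
    ("half growth (alpha0=0.05)", psi.replace(alpha0=0.05)),
    ("weak dispersal (beta0=-4)", psi.replace(beta0=-4.0)),
    ("gamma doubled", psi.replace(gamma=72.76)),
]:
    rng = np.random.default_rng(1)
    ll = gp.log_likelihood(data, land, candidate.growth(),
                           candidate.movement(), candidate.observation(),
                           P, rng)
    print(f"{label:28s} log-lik = {ll:9.1f}")

print()
print("The data discriminate strongly against too-slow growth or dispersal")
print("(-inf: the filter cannot reconcile those with the hunting records")
print("and the spread of positive pellet counts); the likelihood surface")
print("over gamma is flatter, matching its wide reported uncertainty.")
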