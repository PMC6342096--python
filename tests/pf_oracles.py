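"""Shared independent oracles for the particle-filter tests.

The dynamic-programming likelihood here is computed by forward recursion
over an enumerated state space and never calls the particle filter, so it
can serve as an exact reference for the filter's estimates on single-cell
models with an identity dispersal kernel.
"""

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

import gridpop as gp
from gridpop import particle
from gridpop.particle import cell_nmax, pilot_lambda


def one_cell_landscape(area=4.0):
    land = gp.build_lattice(1, 1, 2.0)
    land.area[:] = area
    return land


def one_cell_data(blocks=(), pellets=(), hunts=(), area_b=4.0):
    """Assemble a single-cell SurveyDataset from (year, count) pairs."""
    return gp.SurveyDataset(
        pellet=pd.DataFrame([(0, y, c) for y, c in pellets],
                            columns=["cell", "year", "count"]),
        block=pd.DataFrame([(0, y, c, area_b) for y, c in blocks],
                           columns=["cell", "year", "count", "area_km2"]),
        hunting=pd.DataFrame([(1, y, h) for y, h in hunts],
                             columns=["unit", "year", "total"]),
    )


def exact_one_cell_loglik(data, land, r, obs, config=None, k_max=400):
    """Exact log marginal likelihood by dynamic programming.

    Forward recursion over N ∈ [0, k_max] with the filter's NB(κ, μ)
    initial prior truncated to its own N_max, Poisson growth, exact hunting
    subtraction of the recorded totals, and the pellet/block observation
    pmfs; the dispersal kernel is the identity (single cell).
    """
    config = config or particle.PFConfig()
    lam = pilot_lambda(land, data, None, 0, config)
    mu = max(lam[0], config.lambda_floor)
    nmax = cell_nmax(float(mu), config)
    kap = config.init_kappa

    def obs_loglik_vec(year, states):
        out = np.zeros(states.size)
        for _, row in data.pellet[data.pellet["year"] == year].iterrows():
            out += gp.pellet_loglik(row["count"], states, land.area[0], obs)
        for _, row in data.block[data.block["year"] == year].iterrows():
            out += gp.block_loglik(row["count"], states, land.area[0],
                                   row["area_km2"])
        return out

    states = np.arange(k_max + 1)
    w = np.zeros(k_max + 1)
    w[: nmax + 1] = nbinom.pmf(states[: nmax + 1], kap, kap / (kap + mu))
    w *= np.exp(obs_loglik_vec(0, states))
    t0, t1 = data.year_range()
    for t in range(t0, t1):
        H = data.hunting_at(t).get(1, 0)
        trans = np.zeros((k_max + 1, k_max + 1))
        for n in range(k_max + 1):
            trans[n] = poisson.pmf(states + H, r * n)
        w = w @ trans
        w *= np.exp(obs_loglik_vec(t + 1, states))
    return float(np.log(w.sum()))
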