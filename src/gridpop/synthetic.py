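"""Synthetic landscapes and survey datasets with the structure the analysis
assumes, at desk scale.

The generator emulates the study system's statistical features: spatially
smooth standardized forest covariates, one or two contiguous river lines,
contiguous ~3×3-cell management units, a contiguous initial range covering
~15% of cells, sparse pellet surveys (default 14.3% of cell-years), block
counts in a few units with surveyed sub-areas of 0.95-2.21 km², and
unit-level hunting totals generated by a Binomial(unit abundance, hunt rate)
stand-in policy (real hunting records are conditioned on, never modelled, so
any feasible generator is admissible for testing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .landscape import GridLandscape, build_lattice, standardize_covariates
from .observations import SurveyDataset, allocate_hunting, block_sample, pellet_sample
from .params import Parameters
from .process import initial_state_sample, simulate_trajectory
from .dispersal import build_kernel

import pandas as pd


def default_psi() -> Parameters:
    """Reference parameter vector used throughout the examples and tests:
    α = (0.332, 0.008, −0.004), β = (−1.852, 0.247, −0.184),
    γ = 36.38, θ = 0.368."""
    return Parameters(alpha0=0.332, alpha1=0.008, alpha2=-0.004,
                      beta0=-1.852, beta1=0.247, beta2=-0.184,
                      gamma=36.38, theta=0.368)


def make_landscape(n_rows: int, n_cols: int, seed: int,
                   cell_side: float = 2.0, corr_sigma: float = 1.5,
                   present_frac: float = 0.15, unit_block: int = 3,
                   n_rivers: int = None) -> GridLandscape:
    """Generate a synthetic landscape with smooth covariates.

    BLF/EDGE/FRT are Gaussian-filtered white noise (correlation length ≈ 3
    cells) standardized over cells; rivers are 1-2 contiguous top-to-bottom
    random-walk lines; management units are contiguous ~unit_block² blocks;
    ``present2000`` is one contiguous region grown from a random interior
    seed to ~present_frac of cells.  Habitat areas A_i are U(0.5, 1)× the
    cell area.  Deterministic given the seed.
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("synthetic landscapes need dims >= 4")
    rng = np.random.default_rng(seed)
    land = build_lattice(n_rows, n_cols, cell_side)
    n = land.n
    for name in ("blf", "edge", "frt"):
        smooth = gaussian_filter(rng.standard_normal((n_rows, n_cols)),
                                 corr_sigma, mode="reflect")
        setattr(land, name, smooth.ravel())
    standardize_covariates(land)
    land.area = cell_side ** 2 * rng.uniform(0.5, 1.0, n)

    riv = np.zeros((n_rows, n_cols), dtype=int)
    for _ in range(n_rivers if n_rivers is not None else rng.integers(1, 3)):
        c = int(rng.integers(0, n_cols))
        for r in range(n_rows):
            riv[r, c] = 1
            c = int(np.clip(c + rng.integers(-1, 2), 0, n_cols - 1))
    land.riv = riv.ravel()

    rr, cc = np.divmod(np.arange(n), n_cols)
    n_ucols = -(-n_cols // unit_block)
    land.unit_id = (rr // unit_block) * n_ucols + cc // unit_block + 1

    target = max(1, int(np.ceil(present_frac * n)))
    start = int(rng.integers(0, n))
    region = {start}
    frontier = set(land.neighbors[start].tolist())
    while len(region) < target and frontier:
        pick = int(rng.choice(sorted(frontier)))
        frontier.discard(pick)
        region.add(pick)
        frontier |= set(land.neighbors[pick].tolist()) - region
    present = np.zeros(n, dtype=int)
    present[sorted(region)] = 1
    land.present2000 = present
    return land


@dataclass
class SurveyConfig:
    """Survey design and hunting-policy settings for the generator."""

    pellet_fraction: float = 0.143   # fraction of cell-years with pellet counts
    n_block_units: int = 2           # units with a block-count station
    block_area_range: tuple = (0.95, 2.21)   # A^B, km²
    hunt_rate: float = 0.1           # Binomial harvest rate per unit-year
    init_density: float = 15.0       # seed abundance per occupied cell
    gibbs_sweeps: int = 1            # initial-state smoothing Gibbs sweeps


def simulate_dataset(land: GridLandscape, psi: Parameters, years: int,
                     seed: int, config: SurveyConfig = None,
                     dt: float = 1.0 / 16.0):
    """Simulate a latent trajectory and a matching survey dataset at ψ.

    Returns ``(states, dataset)`` where ``states`` is the list of yearly
    PopulationStates (years+1 survey years, hunting in the first ``years``)
    and ``dataset`` a SurveyDataset drawn from the observation models at ψ.
    Deterministic given (landscape, ψ, seed).
    """
    config = config or SurveyConfig()
    rng = np.random.default_rng(seed)
    growth, move, obs = psi.growth(), psi.movement(dt), psi.observation()
    if not growth.check_cap(land):
        raise ValueError("psi violates the growth-rate cap on this landscape")
    kernel = build_kernel(land, move)

    seed_field = rng.poisson(config.init_density * (land.present2000 != 0))
    initial = initial_state_sample(land, seed_field, config.gibbs_sweeps, rng)

    units = land.units
    hunting_records = []

    def policy(state, rng_):
        H = np.zeros(land.n, dtype=np.int64)
        for k, cells in units.items():
            tot = int(state.N_h[cells].sum())
            Hu = int(rng_.binomial(tot, config.hunt_rate)) if tot else 0
            for _ in range(100):
                alloc, ok = allocate_hunting(state.N_h[cells], Hu, rng_)
                if ok:
                    H[cells] = alloc
                    break
            else:  # pragma: no cover - vanishingly rare with Hu <= total
                H[cells] = np.minimum(state.N_h[cells], Hu)
            hunting_records.append((k, state.year, Hu))
        return H

    states = simulate_trajectory(initial, years, growth, kernel, land, rng,
                                 hunting_policy=policy)
    if states[-1].N_r.sum() == 0:
        warnings.warn("population went extinct before the final year",
                      stacklevel=2)

    n_pellet = max(1, int(np.ceil(config.pellet_fraction * land.n)))
    pellet_rows = []
    for s in states:
        cells = rng.choice(land.n, size=n_pellet, replace=False)
        counts = pellet_sample(s.N_r[cells], land.area[cells], obs, rng)
        pellet_rows += [(int(c), s.year, int(f)) for c, f in zip(cells, counts)]

    unit_ids = sorted(units)
    chosen = rng.choice(unit_ids, size=min(config.n_block_units, len(unit_ids)),
                        replace=False)
    block_rows = []
    for k in chosen:
        cell = int(rng.choice(units[int(k)]))
        a_b = float(min(rng.uniform(*config.block_area_range), land.area[cell]))
        for s in states:
            b = int(block_sample(s.N_r[cell], land.area[cell], a_b, rng))
            block_rows.append((cell, s.year, b, a_b))

    dataset = SurveyDataset(
        pellet=pd.DataFrame(pellet_rows, columns=["cell", "year", "count"]),
        block=pd.DataFrame(block_rows,
                           columns=["cell", "year", "count", "area_km2"]),
        hunting=pd.DataFrame(hunting_records,
                             columns=["unit", "year", "total"]),
    )
    dataset.validate(land)
    return states, dataset
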