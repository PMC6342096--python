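"""Annual demographic cycle: growth -> hunting -> dispersal, plus the
spatially autocorrelated initial state.

Within each year t the latent abundances pass through three stages:

* growth:     N^h_i ~ Poisson(r_i · N^r_i), with log r_i = α0 + α1·BLF_i +
              α2·EDGE_i capped so that max_i r_i < 1.5 (a female produces at
              most one calf per year);
* hunting:    N^d_i = N^h_i − H_i, exact subtraction, requiring N^h_i ≥ H_i;
* dispersal:  destination counts per source drawn from
              Multinomial(N^d_i; row i of the annual kernel M); next year's
              N^r is the column sum of flows, so dispersal conserves the
              total exactly.

The year-2000 initial field follows an auto-model in which each cell is
Poisson with mean proportional to its habitat area times the density of its
neighbourhood; it is sampled by fixed-scan Gibbs sweeps and scored by the
pseudo-likelihood of the full conditionals.  Cells with no evidence of
occupancy in 2000 (present2000 = 0) are pinned at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import gammaln

from .dispersal import MovementKernel
from .landscape import GridLandscape

GROWTH_RATE_CAP = 1.5


class InfeasibleStateError(RuntimeError):
    """Raised when a hunting record exceeds the available abundance."""


@dataclass
class GrowthParams:
    """Log-linear growth-rate parameters: log r_i = α0 + α1·BLF_i + α2·EDGE_i."""

    alpha0: float
    alpha1: float = 0.0
    alpha2: float = 0.0

    def rates(self, land: GridLandscape) -> np.ndarray:
        return np.exp(self.alpha0 + self.alpha1 * land.blf
                      + self.alpha2 * land.edge)

    def check_cap(self, land: GridLandscape) -> bool:
        """True iff max_i r_i < 1.5 over the landscape."""
        r = self.rates(land)
        return bool(np.all(np.isfinite(r)) and r.max() < GROWTH_RATE_CAP)


@dataclass
class PopulationState:
    """Per-cell abundances through one annual cycle.

    ``N_r`` is the spring abundance (before growth); ``N_h`` after growth /
    before hunting; ``N_d`` after hunting / before dispersal; ``H`` the
    per-cell harvest.  Stages not yet reached are None.
    """

    year: int
    N_r: np.ndarray
    N_h: Optional[np.ndarray] = None
    N_d: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    flows: Optional[np.ndarray] = field(default=None, repr=False)


def growth_step(state: PopulationState, growth: GrowthParams,
                land: GridLandscape, rng: np.random.Generator) -> PopulationState:
    """Draw N^h_i ~ Poisson(r_i · N^r_i) independently per cell."""
    r = growth.rates(land)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite growth rate")
    state.N_h = rng.poisson(r * state.N_r).astype(np.int64)
    return state


def hunting_step(state: PopulationState, H: np.ndarray) -> PopulationState:
    """Exact removal N^d = N^h − H; infeasible records raise."""
    H = np.asarray(H, dtype=np.int64)
    if np.any(H > state.N_h):
        raise InfeasibleStateError("hunted count exceeds abundance in a cell")
    state.H = H
    state.N_d = state.N_h - H
    return state


def dispersal_step(state: PopulationState, kernel: MovementKernel,
                   rng: np.random.Generator,
                   keep_flows: bool = False) -> PopulationState:
    """Multinomial redistribution of N^d along rows of the annual kernel.

    Returns the *next* year's state whose N_r is the column sum of flows;
    the total count is conserved exactly.
    """
    M = kernel.annual
    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-8):
        raise ValueError("annual kernel rows do not sum to 1")
    n = state.N_r.size
    out = np.zeros(n, dtype=np.int64)
    flows = np.zeros((n, n), dtype=np.int64) if keep_flows else None
    for i in np.flatnonzero(state.N_d):
        draw = rng.multinomial(int(state.N_d[i]), M[i])
        out += draw
        if keep_flows:
            flows[i] = draw
    nxt = PopulationState(year=state.year + 1, N_r=out)
    if keep_flows:
        state.flows = flows
    return nxt


def dispersal_many(N_d: np.ndarray, M: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized dispersal for a (P, n) batch of abundance fields.

    One batched multinomial per occupied source cell; used by the particle
    filter where P replicate fields move through the same kernel.
    """
    P, n = N_d.shape
    out = np.zeros((P, n), dtype=np.int64)
    for i in np.flatnonzero(N_d.any(axis=0)):
        out += rng.multinomial(N_d[:, i], M[i])
    return out


# ------------------------------------------------------------ initial state

def neighborhood_mean(field: np.ndarray, land: GridLandscape, i: int) -> float:
    """Conditional Poisson mean A_i · Σ_{j∈n_i} N_j / Σ_{j∈n_i} A_j.

    Undefined (returned as nan) for cells with no neighbours.
    """
    nb = land.neighbors[i]
    if nb.size == 0:
        return float("nan")
    return float(land.area[i] * field[nb].sum() / land.area[nb].sum())


def initial_state_sample(land: GridLandscape, seed_field: np.ndarray,
                         n_sweeps: int, rng: np.random.Generator) -> PopulationState:
    """Sample the autocorrelated initial field by fixed-scan Gibbs sweeps.

    Starting from ``seed_field``, each sweep resamples every unmasked cell in
    index order from Poisson(A_i · Σ_{j∈n_i} N_j / Σ_{j∈n_i} A_j); cells with
    present2000 = 0 are pinned at zero throughout.  Cells without neighbours
    keep their seed value.
    """
    field_ = np.asarray(seed_field, dtype=np.int64).copy()
    mask = land.present2000 == 0
    field_[mask] = 0
    for _ in range(n_sweeps):
        for i in range(land.n):
            if mask[i] or land.neighbors[i].size == 0:
                continue
            field_[i] = rng.poisson(neighborhood_mean(field_, land, i))
    return PopulationState(year=0, N_r=field_)


def _poisson_logpmf(k: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Poisson log-pmf with the 0·log 0 = 0 convention at mean 0."""
    k = np.asarray(k, dtype=float)
    mean = np.asarray(mean, dtype=float)
    out = np.where(mean > 0,
                   k * np.log(np.where(mean > 0, mean, 1.0)) - mean - gammaln(k + 1),
                   np.where(k == 0, 0.0, -np.inf))
    return out


def initial_state_logpseudodensity(field: np.ndarray,
                                   land: GridLandscape) -> float:
    """Pseudo-likelihood Σ_i log Poisson(N_i; A_i Σ_{j∈n_i}N_j / Σ_{j∈n_i}A_j).

    Returns −inf if any masked (present2000 = 0) cell is occupied.  Masked
    cells and cells with empty neighbour sets contribute no own-term (the
    former are deterministic, the latter have an undefined conditional).
    """
    field = np.asarray(field, dtype=np.int64)
    mask = land.present2000 == 0
    if np.any(field[mask] != 0):
        return float("-inf")
    total = 0.0
    for i in range(land.n):
        if mask[i] or land.neighbors[i].size == 0:
            continue
        total += float(_poisson_logpmf(field[i], neighborhood_mean(field, land, i)))
        if total == float("-inf"):
            break
    return total


def initial_pseudodensity_many(fields: np.ndarray,
                               land: GridLandscape) -> np.ndarray:
    """Vectorized pseudo-likelihood for a (P, n) batch of fields."""
    fields = np.asarray(fields, dtype=np.int64)
    mask = land.present2000 == 0
    n = land.n
    # neighbour sums via an adjacency matrix product
    import scipy.sparse as sp
    rows = np.concatenate([np.full(land.neighbors[i].size, i) for i in range(n)]) \
        if n else np.array([], dtype=int)
    cols = np.concatenate(land.neighbors) if n else np.array([], dtype=int)
    Adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    nb_counts = fields @ Adj.T.toarray()
    nb_area = Adj @ land.area
    with np.errstate(divide="ignore", invalid="ignore"):
        means = land.area * nb_counts / nb_area
    terms = _poisson_logpmf(fields, means)
    keep = ~mask & np.array([nb.size > 0 for nb in land.neighbors])
    total = terms[:, keep].sum(axis=1)
    total[np.any(fields[:, mask] != 0, axis=1)] = -np.inf
    return total


# ------------------------------------------------------------- trajectories

HuntingPolicy = Callable[[PopulationState, np.random.Generator], np.ndarray]


def no_hunting(state: PopulationState, rng: np.random.Generator) -> np.ndarray:
    return np.zeros_like(state.N_h)


def simulate_trajectory(initial: PopulationState, years: int,
                        growth: GrowthParams, kernel: MovementKernel,
                        land: GridLandscape, rng: np.random.Generator,
                        hunting_policy: HuntingPolicy = no_hunting) -> list:
    """Run the annual cycle for ``years`` years, recording every stage.

    ``hunting_policy(state_after_growth, rng)`` returns the per-cell harvest;
    the default takes nothing.  Returns the list of PopulationStates from the
    initial year through year ``initial.year + years`` (the last state holds
    only N_r).
    """
    states = [initial]
    cur = initial
    for _ in range(years):
        growth_step(cur, growth, land, rng)
        hunting_step(cur, hunting_policy(cur, rng))
        nxt = dispersal_step(cur, kernel, rng)
        states.append(nxt)
        cur = nxt
    return states


def trajectory_to_frame(states: list):
    """Long-format table ``year,cell_id,N_r,N_h,N_d,H`` for export."""
    import pandas as pd

    recs = []
    for s in states:
        n = s.N_r.size
        recs.append(pd.DataFrame({
            "year": s.year, "cell_id": np.arange(1, n + 1),
            "N_r": s.N_r,
            "N_h": s.N_h if s.N_h is not None else -1,
            "N_d": s.N_d if s.N_d is not None else -1,
            "H": s.H if s.H is not None else -1,
        }))
    return pd.concat(recs, ignore_index=True)
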