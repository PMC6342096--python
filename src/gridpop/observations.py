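"""Survey observation models: pellet counts, block counts, hunting records.

Three data streams connect the latent spring abundance N^r to observations:

* fecal pellet counts F_{i,t} ~ NegBin(shape θ, rate θ·A_i/(γ·N^r_{i,t})),
  i.e. mean γ·N^r/A (pellets proportional to deer density, with γ pellets per
  unit density) and variance mean + mean²/θ;
* block counts B_{i,t} ~ Poisson(A^B_i · N^r_{i,t} / A_i) for a surveyed
  sub-area A^B_i of cell i;
* unit hunting totals H^u_{k,t}, conditioned on (not modelled); their latent
  allocation to cells is Multinomial(H^u; p ∝ N^h within the unit), which
  assumes a constant within-unit hunting rate.

When N^r = 0 both count models degenerate to a point mass at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson


@dataclass
class ObservationParams:
    """γ: pellets per unit deer density (> 0); θ: NB dispersion (> 0)."""

    gamma: float
    theta: float

    def __post_init__(self):
        if not (self.gamma > 0 and self.theta > 0):
            raise ValueError("gamma and theta must be positive")


def pellet_loglik(F, N_r, A, params: ObservationParams):
    """Log NB pmf of a pellet count given abundance; vectorizes over inputs.

    Shape θ, rate b = θ·A/(γ·N_r), so p = b/(1+b) in the (n, p) convention.
    N_r = 0 is a point mass at F = 0.
    """
    F = np.asarray(F, dtype=float)
    N_r = np.asarray(N_r, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("cell area must be positive")
    safe_N = np.where(N_r > 0, N_r, 1.0)
    b = params.theta * A / (params.gamma * safe_N)
    with np.errstate(divide="ignore"):
        ll = nbinom.logpmf(F, params.theta, b / (1.0 + b))
    out = np.where(N_r > 0, ll, np.where(F == 0, 0.0, -np.inf))
    return out if out.ndim else float(out)


def pellet_sample(N_r, A, params: ObservationParams,
                  rng: np.random.Generator):
    """Draw pellet counts from the NB observation model."""
    N_r = np.asarray(N_r, dtype=float)
    A = np.asarray(A, dtype=float)
    safe_N = np.where(N_r > 0, N_r, 1.0)
    b = params.theta * A / (params.gamma * safe_N)
    draw = rng.negative_binomial(params.theta, b / (1.0 + b), size=N_r.shape)
    return np.where(N_r > 0, draw, 0)


def block_loglik(B, N_r, A, A_B):
    """Log Poisson pmf of a block count with mean A^B · N^r / A."""
    B = np.asarray(B, dtype=float)
    N_r = np.asarray(N_r, dtype=float)
    A = np.asarray(A, dtype=float)
    A_B = np.asarray(A_B, dtype=float)
    if np.any(A_B <= 0) or np.any(A_B > A):
        raise ValueError("block area must satisfy 0 < A_B <= A")
    mean = A_B * N_r / A
    with np.errstate(divide="ignore"):
        ll = poisson.logpmf(B, np.where(mean > 0, mean, 1.0))
    out = np.where(mean > 0, ll, np.where(B == 0, 0.0, -np.inf))
    return out if out.ndim else float(out)


def block_sample(N_r, A, A_B, rng: np.random.Generator):
    """Draw block counts from the Poisson observation model."""
    mean = np.asarray(A_B, dtype=float) * np.asarray(N_r, dtype=float) \
        / np.asarray(A, dtype=float)
    return rng.poisson(mean)


def allocate_hunting(N_h: np.ndarray, H_u: int,
                     rng: np.random.Generator) -> Tuple[Optional[np.ndarray], bool]:
    """Allocate a unit hunting total to cells, Multinomial(H_u; p ∝ N_h).

    Returns ``(H, feasible)``.  Infeasible cases — unit abundance below the
    recorded total, or a draw taking more from a cell than it holds — return
    ``(None, False)`` / ``(H, False)`` and are *not* redrawn: in the particle
    filter they zero the particle's weight, matching the support restriction
    N^h ≥ H.
    """
    N_h = np.asarray(N_h, dtype=np.int64)
    H_u = int(H_u)
    if H_u < 0:
        raise ValueError("hunting total must be nonnegative")
    if H_u == 0:
        return np.zeros_like(N_h), True
    total = int(N_h.sum())
    if total < H_u:
        return None, False
    H = rng.multinomial(H_u, N_h / total)
    return H, bool(np.all(H <= N_h))


# ------------------------------------------------------------------ dataset

@dataclass
class SurveyDataset:
    """Pellet, block and hunting tables over a common year range.

    Tables use 0-based internal cell indices in the ``cell`` column (the CSV
    interface converts to/from 1-based ``cell_id``):

    * ``pellet``:  cell, year, count
    * ``block``:   cell, year, count, area_km2  (A^B, the surveyed sub-area)
    * ``hunting``: unit, year, total            (H^u per management unit)
    """

    pellet: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell", "year", "count"]))
    block: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell", "year", "count", "area_km2"]))
    hunting: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["unit", "year", "total"]))

    def validate(self, land=None) -> None:
        for df, col in ((self.pellet, "count"), (self.block, "count"),
                        (self.hunting, "total")):
            if len(df) and (df[col] < 0).any():
                raise ValueError("survey counts must be nonnegative")
        if land is not None:
            for df in (self.pellet, self.block):
                if len(df) and (df["cell"].max() >= land.n or df["cell"].min() < 0):
                    raise ValueError("survey cell outside the landscape")
            if len(self.block):
                a = land.area[self.block["cell"].to_numpy(int)]
                ab = self.block["area_km2"].to_numpy(float)
                if np.any(ab <= 0) or np.any(ab > a + 1e-9):
                    raise ValueError("block survey area must satisfy 0 < A_B <= A_i")

    @property
    def is_empty(self) -> bool:
        return not (len(self.pellet) or len(self.block) or len(self.hunting))

    def year_range(self) -> Tuple[int, int]:
        """(first, last) year spanned by the data.

        Hunting in year t drives the transition to t+1, so a hunting record at
        t extends the range to t+1.  An empty dataset spans (0, 0).
        """
        years = []
        for df in (self.pellet, self.block):
            if len(df):
                years += [int(df["year"].min()), int(df["year"].max())]
        if len(self.hunting):
            years += [int(self.hunting["year"].min()),
                      int(self.hunting["year"].max()) + 1]
        if not years:
            return 0, 0
        return min(years), max(years)

    def pellet_at(self, year: int) -> pd.DataFrame:
        return self.pellet[self.pellet["year"] == year]

    def block_at(self, year: int) -> pd.DataFrame:
        return self.block[self.block["year"] == year]

    def hunting_at(self, year: int) -> dict:
        sub = self.hunting[self.hunting["year"] == year]
        return {int(u): int(t) for u, t in zip(sub["unit"], sub["total"])}

    # ------------------------------------------------------------------ I/O

    def to_csv(self, pellet_path, block_path, hunting_path) -> None:
        p = self.pellet.copy()
        p["cell_id"] = p.pop("cell") + 1
        p.rename(columns={"count": "pellets"})[
            ["cell_id", "year", "pellets"]].to_csv(pellet_path, index=False)
        b = self.block.copy()
        b["cell_id"] = b.pop("cell") + 1
        b[["cell_id", "year", "count", "area_km2"]].to_csv(block_path, index=False)
        h = self.hunting.copy()
        h.rename(columns={"unit": "unit_id", "total": "hunted"})[
            ["unit_id", "year", "hunted"]].to_csv(hunting_path, index=False)

    @classmethod
    def from_csv(cls, pellet_path, block_path, hunting_path) -> "SurveyDataset":
        p = pd.read_csv(pellet_path)
        p["cell"] = p.pop("cell_id") - 1
        p = p.rename(columns={"pellets": "count"})[["cell", "year", "count"]]
        b = pd.read_csv(block_path)
        b["cell"] = b.pop("cell_id") - 1
        b = b[["cell", "year", "count", "area_km2"]]
        h = pd.read_csv(hunting_path).rename(
            columns={"unit_id": "unit", "hunted": "total"})[["unit", "year", "total"]]
        return cls(pellet=p, block=b, hunting=h)
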