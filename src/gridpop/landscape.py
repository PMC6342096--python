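"""Discretized landscape: lattice cells, habitat areas, covariates, adjacency.

The study region is a rectangular lattice of square cells (default 2 km on a
side).  Each cell carries a habitat area ``A_i`` (km²), standardized
environmental covariates (broad-leaf forest area BLF, forest-edge length EDGE,
total forest area FRT), a binary river indicator RIV, a management-unit label,
and an indicator of occupancy at the start of the study (``present2000``).

Adjacency is queen (8-cell) adjacency; inter-cell distances are expressed in
grid-cell units: 1 for rook neighbours, sqrt(2) for diagonal neighbours, 0 for
a cell and itself.  Physical distances in km are obtained by multiplying with
``cell_side``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SQRT2 = float(np.sqrt(2.0))

#: continuous covariates that are z-scored over cells
COVARIATE_COLUMNS = ("blf", "edge", "frt")

#: column layout of the landscape CSV interface
CSV_COLUMNS = (
    "cell_id", "x_km", "y_km", "area_km2",
    "blf", "edge", "frt", "riv", "unit_id", "present2000",
)

_QUEEN_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                  (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class GridLandscape:
    """A lattice of grid cells with areas, covariates and neighbour structure.

    Cells are indexed ``0..n-1`` internally; the CSV interface uses 1-based
    ``cell_id``.  ``neighbors[i]`` lists the in-domain queen neighbours of
    cell ``i`` and ``neighbor_dist[i]`` the matching distances in grid-cell
    units (1 or sqrt(2)).
    """

    x: np.ndarray                    # cell-center x, km
    y: np.ndarray                    # cell-center y, km
    area: np.ndarray                 # habitat area A_i, km² (> 0)
    blf: np.ndarray                  # standardized broad-leaf forest area
    edge: np.ndarray                 # standardized forest-edge length
    frt: np.ndarray                  # standardized total forest area
    riv: np.ndarray                  # river presence, 0/1
    unit_id: np.ndarray              # management-unit label per cell
    present2000: np.ndarray          # initial-range indicator, 0/1
    cell_side: float = 2.0           # lattice spacing, km
    neighbors: list = field(default_factory=list, repr=False)
    neighbor_dist: list = field(default_factory=list, repr=False)
    standardization: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def units(self) -> dict:
        """Map unit label -> array of member cell indices (a partition)."""
        out: dict = {}
        for k in np.unique(self.unit_id):
            out[int(k)] = np.flatnonzero(self.unit_id == k)
        return out

    def validate(self) -> None:
        if np.any(self.area <= 0):
            raise ValueError("habitat areas A_i must be positive")
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency between {i} and {j}")

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(1, self.n + 1),
            "x_km": self.x, "y_km": self.y, "area_km2": self.area,
            "blf": self.blf, "edge": self.edge, "frt": self.frt,
            "riv": self.riv.astype(int), "unit_id": self.unit_id.astype(int),
            "present2000": self.present2000.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_side: float = 2.0) -> "GridLandscape":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"landscape table missing columns: {missing}")
        if df[list(CSV_COLUMNS)].isna().any().any():
            raise ValueError("landscape table contains missing values")
        df = df.sort_values("cell_id").reset_index(drop=True)
        land = cls(
            x=df["x_km"].to_numpy(float), y=df["y_km"].to_numpy(float),
            area=df["area_km2"].to_numpy(float),
            blf=df["blf"].to_numpy(float), edge=df["edge"].to_numpy(float),
            frt=df["frt"].to_numpy(float), riv=df["riv"].to_numpy(int),
            unit_id=df["unit_id"].to_numpy(int),
            present2000=df["present2000"].to_numpy(int),
            cell_side=float(cell_side),
        )
        _attach_lattice_adjacency(land)
        return land

    @classmethod
    def from_csv(cls, path, cell_side: float = 2.0) -> "GridLandscape":
        return cls.from_frame(pd.read_csv(path), cell_side=cell_side)


def _attach_lattice_adjacency(land: GridLandscape) -> None:
    """Rebuild queen adjacency from cell-center coordinates."""
    side = land.cell_side
    cols = np.rint(land.x / side - 0.5).astype(int)
    rows = np.rint(land.y / side - 0.5).astype(int)
    index = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    neighbors, dists = [], []
    for i in range(land.n):
        nb, dd = [], []
        for dr, dc in _QUEEN_OFFSETS:
            j = index.get((rows[i] + dr, cols[i] + dc))
            if j is not None:
                nb.append(j)
                dd.append(1.0 if dr == 0 or dc == 0 else SQRT2)
        neighbors.append(np.asarray(nb, dtype=np.intp))
        dists.append(np.asarray(dd, dtype=float))
    land.neighbors = neighbors
    land.neighbor_dist = dists


def build_lattice(n_rows: int, n_cols: int, cell_side: float = 2.0) -> GridLandscape:
    """Build a rectangular lattice with queen adjacency and zeroed covariates.

    Cell centers sit at ``(col + 0.5) * cell_side, (row + 0.5) * cell_side``;
    cells are ordered row-major.  Areas default to the full cell area
    ``cell_side**2``; covariates to 0; every cell is its own management unit 1
    and marked present.
    """
    if n_rows < 1 or n_cols < 1 or cell_side <= 0:
        raise ValueError("lattice dimensions and cell side must be positive")
    n = n_rows * n_cols
    rr, cc = np.divmod(np.arange(n), n_cols)
    land = GridLandscape(
        x=(cc + 0.5) * cell_side, y=(rr + 0.5) * cell_side,
        area=np.full(n, cell_side ** 2, dtype=float),
        blf=np.zeros(n), edge=np.zeros(n), frt=np.zeros(n),
        riv=np.zeros(n, dtype=int),
        unit_id=np.ones(n, dtype=int),
        present2000=np.ones(n, dtype=int),
        cell_side=float(cell_side),
    )
    _attach_lattice_adjacency(land)
    return land


def standardize_covariates(land: GridLandscape) -> GridLandscape:
    """Z-score the continuous covariates (BLF, EDGE, FRT) over cells, in place.

    Uses the population standard deviation (ddof=0).  The binary river
    indicator is left untouched.  The (mean, sd) pairs used are stored in
    ``land.standardization`` so the transform is invertible.

    Raises
    ------
    ValueError
        If the landscape has fewer than two cells or a covariate column is
        constant (zero variance), naming the offending column.
    """
    if land.n < 2:
        raise ValueError("standardization needs at least two cells")
    for name in COVARIATE_COLUMNS:
        col = getattr(land, name).astype(float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        mu, sd = float(col.mean()), float(col.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} has zero variance")
        setattr(land, name, (col - mu) / sd)
        land.standardization[name] = (mu, sd)
    return land


def neighbor_sets(land: GridLandscape) -> dict:
    """Return ``{i: [(j, DIST_ij), ...]}`` over in-domain queen neighbours.

    Distances are in grid-cell units (1 rook, sqrt(2) diagonal); the self
    distance DIST_ii is 0 by convention and the self cell is not listed.
    """
    return {
        i: list(zip(land.neighbors[i].tolist(), land.neighbor_dist[i].tolist()))
        for i in range(land.n)
    }
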