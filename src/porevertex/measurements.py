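"""Ensemble statistics of the growing tissue.

At every output time the simulator records the cell count ``N(t)`` and
the population means, normalized by the reference cell:

    A1 = <A_i>/A0,   L1 = <L_i>/L0,   p1 = <A0/A_i - 1>,   E1 = <E_i>,

together with the polygon-class census (the fraction of cells with a
given side count).  The dimensionless cell pressure ``A0/A - 1`` is the
bubble analogy: zero for a relaxed hexagon, positive for compressed
cells, negative for inflated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TissueMesh
from .mechanics import MechParams, cell_energy

__all__ = [
    "TimeSeriesRecord",
    "cell_pressure",
    "ensemble_stats",
    "shape_census",
    "ensemble_average",
    "records_to_frame",
]

#: side-count columns written to time-series tables
CENSUS_BINS = list(range(3, 10))


@dataclass
class TimeSeriesRecord:
    """One output-time snapshot of the population statistics."""

    t: float
    N: int
    A1: float
    L1: float
    p1: float
    E1: float
    census: dict[int, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {"t": self.t, "N": self.N, "A1": self.A1, "L1": self.L1,
               "p1": self.p1, "E1": self.E1}
        for b in CENSUS_BINS:
            row[f"frac_{b}"] = self.census.get(b, 0.0)
        row["frac_ge10"] = sum(v for k, v in self.census.items() if k >= 10)
        return row


def cell_pressure(A: float, A0: float) -> float:
    """Dimensionless pressure ``A0/A - 1`` inside a cell of area ``A``."""
    if A <= 0:
        raise ValueError("cell area must be positive")
    return A0 / A - 1.0


def shape_census(mesh: TissueMesh) -> dict[int, float]:
    """Fraction of cells per side count; fractions sum to one."""
    if mesh.n_cells == 0:
        raise ValueError("census undefined for an empty mesh")
    counts: dict[int, int] = {}
    for cell in mesh.cells.values():
        counts[cell.n_sides] = counts.get(cell.n_sides, 0) + 1
    n = mesh.n_cells
    return {k: v / n for k, v in sorted(counts.items())}


def ensemble_stats(mesh: TissueMesh, params: MechParams,
                   t: float = 0.0) -> TimeSeriesRecord:
    """Population means over all cells of the mesh at time ``t``."""
    if mesh.n_cells == 0:
        raise ValueError("statistics undefined for an empty mesh")
    areas = np.array([mesh.cell_area(c) for c in sorted(mesh.cells)])
    perims = np.array([mesh.cell_perimeter(c) for c in sorted(mesh.cells)])
    energies = np.array([cell_energy(L, A, params) for L, A in zip(perims, areas)])
    return TimeSeriesRecord(
        t=t,
        N=mesh.n_cells,
        A1=float(areas.mean()) / params.A0,
        L1=float(perims.mean()) / params.L0,
        p1=float(np.mean(params.A0 / areas - 1.0)),
        E1=float(energies.mean()),
        census=shape_census(mesh),
    )


def stats_from_arrays(t: float, L: np.ndarray, A: np.ndarray,
                      n_sides: np.ndarray, params: MechParams) -> TimeSeriesRecord:
    """Population means from precomputed per-cell arrays (fast path).

    Produces exactly the same record as :func:`ensemble_stats` computed
    on the mesh the arrays were derived from.
    """
    if len(A) == 0:
        raise ValueError("statistics undefined for an empty mesh")
    energies = 0.5 * (params.mu * (L - params.L0) ** 2
                      + params.eta * (A - params.A0) ** 2)
    counts = np.bincount(n_sides.astype(np.int64))
    census = {int(k): counts[k] / len(A) for k in np.nonzero(counts)[0]}
    return TimeSeriesRecord(
        t=t,
        N=int(len(A)),
        A1=float(A.mean()) / params.A0,
        L1=float(L.mean()) / params.L0,
        p1=float(np.mean(params.A0 / A - 1.0)),
        E1=float(energies.mean()),
        census=census,
    )


def records_to_frame(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def ensemble_average(trajectories) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pointwise mean and standard deviation across realizations.

    Accepts a list of record lists or DataFrames sharing an output-time
    grid.  If the grids differ, every trajectory is interpolated onto the
    coarsest common grid (with a warning).  Returns ``(mean, std)``
    frames indexed like the inputs.
    """
    frames = [
        tr if isinstance(tr, pd.DataFrame) else records_to_frame(tr)
        for tr in trajectories
    ]
    if not frames:
        raise ValueError("need at least one trajectory")
    grids = [f["t"].to_numpy() for f in frames]
    base = min(grids, key=len)
    if any(len(g) != len(base) or not np.allclose(g, base) for g in grids):
        warnings.warn("trajectories on different time grids; interpolating "
                      "onto the coarsest grid")
        cols = frames[0].columns.drop("t")
        frames = [
            pd.DataFrame(
                {"t": base, **{c: np.interp(base, f["t"], f[c]) for c in cols}}
            )
            for f in frames
        ]
    stack = np.stack([f.to_numpy(dtype=float) for f in frames])
    mean = pd.DataFrame(stack.mean(axis=0), columns=frames[0].columns)
    std = pd.DataFrame(stack.std(axis=0, ddof=0), columns=frames[0].columns)
    std["t"] = mean["t"]
    return mean, std
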