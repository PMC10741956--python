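"""Elastic energy, node forces and threshold overdamped vertex motion.

Each cell carries the elastic energy

    E_i = 1/2 [ mu (L_i - L0)^2 + eta (A_i - A0)^2 ],

with reference perimeter ``L0 = 3 a`` and area ``A0 = (3 sqrt(3)/8) a^2``
of a regular hexagon of diameter ``a``.  Nodes move without inertia:
the force on a node sets its velocity directly, ``v = k F``, but only
once the squared force magnitude exceeds the threshold ``F0`` (the
printed model thresholds ``|F|^2``; set ``threshold_on_magnitude`` to
compare ``|F|`` instead).  Nodes on the pore wall obey a slip condition:
the wall-normal velocity component is removed and the node slides along
the wall curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._flat import compile_mesh
from .geometry import ChannelGeometry, TissueMesh

__all__ = [
    "MechParams",
    "cell_energy",
    "total_energy",
    "node_forces",
    "apply_slip",
    "choose_timestep",
    "step_nodes",
]

#: Courant safety factor: the step never moves a node further than this
#: fraction of the shortest edge.
COURANT_FACTOR = 0.1


@dataclass(frozen=True)
class MechParams:
    """Mechanical constants of the tissue (reference-parameter set).

    Defaults are the calibrated values for a cell of diameter ``a = 2``:
    mu=1, eta=4, k=0.5, F0=0.1, L0=6, A0=3*sqrt(3)/2.
    """

    mu: float = 1.0
    eta: float = 4.0
    k: float = 0.5
    F0: float = 0.1
    L0: float = 6.0
    A0: float = 3.0 * math.sqrt(3.0) / 2.0
    dt: float = 0.01
    threshold_on_magnitude: bool = False

    def __post_init__(self):
        for name in ("mu", "eta", "k", "F0", "L0", "A0", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_cell_diameter(cls, a: float = 2.0, **kw) -> "MechParams":
        """Build parameters with ``L0 = 3a`` and ``A0 = (sqrt(3)/24) L0^2``."""
        L0 = 3.0 * a
        return cls(L0=L0, A0=math.sqrt(3.0) / 24.0 * L0 * L0, **kw)

    def with_(self, **kw) -> "MechParams":
        return replace(self, **kw)


def cell_energy(L: float, A: float, params: MechParams) -> float:
    """Elastic energy of one cell given its perimeter and area."""
    return 0.5 * (
        params.mu * (L - params.L0) ** 2 + params.eta * (A - params.A0) ** 2
    )


def total_energy(mesh: TissueMesh, params: MechParams) -> float:
    """Sum of the per-cell elastic energies over the whole tissue."""
    return sum(
        cell_energy(mesh.cell_perimeter(c), mesh.cell_area(c), params)
        for c in mesh.cells
    )


def node_forces(mesh: TissueMesh, params: MechParams) -> np.ndarray:
    """Analytic ``-dE/dR`` for every vertex, shape ``(n_vertices, 2)``.

    Every vertex accumulates a perimeter-tension contribution (sum of unit
    edge vectors) and an area-elasticity contribution (shoelace gradient)
    from each incident cell.  Matches a central-difference gradient of
    :func:`total_energy` to high accuracy.
    """
    flat = compile_mesh(mesh)
    L, A, _, _, _ = _kernels.geometry_pass(
        mesh.positions, flat.corner_cell, flat.corner_vert, flat.next_vert,
        flat.n_cells,
    )
    return _kernels.force_pass(
        mesh.positions, flat.corner_cell, flat.corner_vert,
        flat.next_vert, flat.prev_vert,
        L, A, params.mu, params.eta, params.L0, params.A0, mesh.n_vertices,
    )


def apply_slip(velocity, normal) -> np.ndarray:
    """Remove the wall-normal component: ``v - (v.n) n``."""
    v = np.asarray(velocity, dtype=float)
    n = np.asarray(normal, dtype=float)
    return v - np.dot(v, n) * n


def node_velocities(forces: np.ndarray, params: MechParams) -> np.ndarray:
    """Thresholded overdamped velocities ``v = k F H(|F|^2 - F0)``.

    The Heaviside convention is ``H(0) = 0``: a force exactly at the
    threshold does not move its node.
    """
    f2 = np.einsum("ij,ij->i", forces, forces)
    crit = np.sqrt(f2) > params.F0 if params.threshold_on_magnitude else f2 > params.F0
    return params.k * forces * crit[:, None]


def choose_timestep(mesh: TissueMesh, forces: np.ndarray,
                    params: MechParams) -> float:
    """Courant-limited step: ``min(dt, c l_min / v_max)`` with c = 0.1."""
    flat = compile_mesh(mesh)
    _, _, _, _, lmin = _kernels.geometry_pass(
        mesh.positions, flat.corner_cell, flat.corner_vert, flat.next_vert,
        flat.n_cells,
    )
    speeds = np.linalg.norm(node_velocities(forces, params), axis=1)
    vmax = float(speeds.max()) if speeds.size else 0.0
    if vmax == 0.0:
        return params.dt
    return min(params.dt, COURANT_FACTOR * lmin / vmax)


def step_nodes(mesh: TissueMesh, forces: np.ndarray, params: MechParams,
               geom: ChannelGeometry) -> float:
    """Advance all vertices one explicit-Euler step; returns the dt taken.

    Applies, in order: the motion threshold, the slip projection for
    wall-attached vertices (with release when the velocity points into
    the fluid), the displacement, confinement of vertices that crossed a
    wall, and the re-snap of wall vertices onto the wall curve.
    """
    flat = compile_mesh(mesh)
    _, _, _, _, lmin = _kernels.geometry_pass(
        mesh.positions, flat.corner_cell, flat.corner_vert, flat.next_vert,
        flat.n_cells,
    )
    return _kernels.step_pass(
        mesh.positions, mesh.wall_mask, forces,
        params.k, params.F0, params.threshold_on_magnitude,
        params.dt, COURANT_FACTOR, lmin,
        geom.h, geom.epsilon, geom.wavenumber, geom.phase,
        geom.x_min, geom.x_max, geom.closed_ends,
    )


# ---------------------------------------------------------------------------
# pure-python reference (used to cross-check the compiled kernels)
# ---------------------------------------------------------------------------

def node_forces_reference(mesh: TissueMesh, params: MechParams) -> np.ndarray:
    """Object-level force assembly, independent of the numba kernels."""
    F = np.zeros((mesh.n_vertices, 2))
    pos = mesh.positions
    for cell in mesh.cells.values():
        ids = cell.vertex_ids
        n = len(ids)
        pts = pos[ids]
        L = float(np.sum(np.linalg.norm(np.roll(pts, -1, 0) - pts, axis=1)))
        x, y = pts[:, 0], pts[:, 1]
        A = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        cL = params.mu * (L - params.L0)
        cA = params.eta * (A - params.A0)
        for i in range(n):
            p = pts[i]
            pn = pts[(i + 1) % n]
            pp = pts[(i - 1) % n]
            g = np.zeros(2)
            for other in (pn, pp):
                d = p - other
                dn = np.linalg.norm(d)
                if dn > 1e-12:
                    g += d / dn
            dA = 0.5 * np.array([pn[1] - pp[1], pp[0] - pn[0]])
            F[ids[i]] -= cL * g + cA * dA
    return F
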