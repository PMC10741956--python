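"""Polygonal-mesh data structures and channel-wall geometry.

The tissue is a conformal planar mesh of polygonal cells that share
vertices and edges.  Cells are stored counter-clockwise; every interior
edge is incident to exactly two cells, every wall or free-front edge to
exactly one.  The scaffold pore is a 2-D channel whose walls follow the
harmonic law ``y = +/- h (1 + eps sin(K x + phase))``; ``eps = 0``
recovers a straight channel.

Lengths are expressed in the same units as the reference cell diameter
``a`` (no physical unit conversion happens inside the simulator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WALL_NONE",
    "WALL_TOP",
    "WALL_BOTTOM",
    "WALL_INLET",
    "WALL_OUTLET",
    "InvalidPolygonError",
    "MeshConformityError",
    "Vertex",
    "Cell",
    "ChannelGeometry",
    "TissueMesh",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "regular_hexagon",
    "wall_half_width",
    "wall_normal",
    "snap_to_wall",
]

# Wall attachment is a bitmask so that a vertex pinned in a channel corner
# can sit on two walls at once (e.g. bottom + inlet).
WALL_NONE = 0
WALL_TOP = 1
WALL_BOTTOM = 2
WALL_INLET = 4
WALL_OUTLET = 8

_SIDE_BITS = {
    "top": WALL_TOP,
    "bottom": WALL_BOTTOM,
    "inlet": WALL_INLET,
    "outlet": WALL_OUTLET,
}


class InvalidPolygonError(ValueError):
    """Raised when fewer than three points are supplied for a polygon."""


class MeshConformityError(RuntimeError):
    """Raised when the mesh stops being a conformal tiling."""


# ---------------------------------------------------------------------------
# polygon measures
# ---------------------------------------------------------------------------

def polygon_area(points) -> float:
    """Signed shoelace area of a polygon.

    Positive for counter-clockwise input, negative for clockwise; zero for
    degenerate (collinear) rings.  Raises :class:`InvalidPolygonError` for
    fewer than three points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidPolygonError("a polygon needs at least 3 planar points")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_perimeter(points) -> float:
    """Sum of Euclidean edge lengths, closing edge included."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidPolygonError("a polygon needs at least 3 planar points")
    return float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))


def polygon_centroid(points) -> np.ndarray:
    """Area centroid; falls back to the vertex mean for degenerate rings."""
    pts = np.asarray(points, dtype=float)
    a = polygon_area(pts)
    if abs(a) < 1e-14:
        return pts.mean(axis=0)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return np.array([cx, cy])


def regular_hexagon(a: float, center=(0.0, 0.0), angle: float = 0.0) -> np.ndarray:
    """Vertices of a regular hexagon of diameter ``a`` (side ``a/2``).

    The default orientation places vertices at multiples of 60 degrees
    starting on the +x axis, which gives horizontal top and bottom edges
    ("flat-top" in the channel frame).  Counter-clockwise order.
    """
    r = 0.5 * a
    th = angle + np.arange(6) * (np.pi / 3.0)
    return np.column_stack(
        [center[0] + r * np.cos(th), center[1] + r * np.sin(th)]
    )


# ---------------------------------------------------------------------------
# channel geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGeometry:
    """Pore channel bounded by ``y = +/- h (1 + eps sin(K x + phase))``.

    Parameters
    ----------
    h : float
        Channel half-width (length units).
    epsilon : float
        Waviness amplitude, ``0 <= eps < 1``; 0 gives a straight channel.
    wavenumber : float
        Wavenumber ``K`` of the wall undulation (1/length).
    phase : float
        Phase of the wall law, radians.  ``-pi/2`` starts the channel at a
        bottleneck.
    x_min, x_max : float
        Axial extent of the pore.
    closed_ends : bool
        If True both ends act as slip walls, so the tissue eventually
        occupies a finite volume.
    """

    h: float = 4.5
    epsilon: float = 0.0
    wavenumber: float = 1.0 / 6.0
    phase: float = 0.0
    x_min: float = 0.0
    x_max: float = 120.0
    closed_ends: bool = True

    def __post_init__(self):
        if not (self.h > 0):
            raise ValueError("h must be positive")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must satisfy 0 <= eps < 1")
        if not (self.x_max > self.x_min):
            raise ValueError("x_max must exceed x_min")

    def half_width(self, x):
        """Wall half-width ``h (1 + eps sin(K x + phase))`` at ``x``."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x_min - 1e-9) or np.any(x > self.x_max + 1e-9):
            raise ValueError("x outside the channel extent")
        w = self.h * (1.0 + self.epsilon * np.sin(self.wavenumber * x + self.phase))
        return float(w) if w.ndim == 0 else w

    def wall_slope(self, x):
        """d(half-width)/dx of the top wall at ``x``."""
        x = np.asarray(x, dtype=float)
        s = self.h * self.epsilon * self.wavenumber * np.cos(
            self.wavenumber * x + self.phase
        )
        return float(s) if s.ndim == 0 else s

    def area(self) -> float:
        """Exact area enclosed by the two walls and the two ends."""
        k, ph = self.wavenumber, self.phase
        span = self.x_max - self.x_min
        if self.epsilon == 0.0 or k == 0.0:
            return 2.0 * self.h * span
        integral = span - (self.epsilon / k) * (
            math.cos(k * self.x_max + ph) - math.cos(k * self.x_min + ph)
        )
        return 2.0 * self.h * integral

    def contains(self, x, y, tol: float = 1e-9) -> bool:
        if not (self.x_min - tol <= x <= self.x_max + tol):
            return False
        return abs(y) <= self.half_width(np.clip(x, self.x_min, self.x_max)) + tol


def wall_half_width(x, geom: ChannelGeometry):
    """Module-level alias of :meth:`ChannelGeometry.half_width`."""
    return geom.half_width(x)


def wall_normal(x: float, side: str, geom: ChannelGeometry) -> np.ndarray:
    """Unit normal of the named wall at ``x``, oriented into the fluid.

    The top/bottom wall tangent is ``(1, +/- h eps K cos(K x + phase))``;
    the returned vector is orthogonal to it.
    """
    if side == "inlet":
        return np.array([1.0, 0.0])
    if side == "outlet":
        return np.array([-1.0, 0.0])
    s = geom.wall_slope(x)
    norm = math.hypot(1.0, s)
    if side == "top":
        return np.array([s, -1.0]) / norm
    if side == "bottom":
        return np.array([s, 1.0]) / norm
    raise ValueError(f"unknown wall side {side!r}")


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class Vertex:
    """Lightweight view of one mesh node."""

    id: int
    position: np.ndarray
    wall_mask: int = WALL_NONE

    @property
    def on_wall(self) -> bool:
        return self.wall_mask != WALL_NONE

    @property
    def wall_sides(self) -> tuple[str, ...]:
        return tuple(s for s, b in _SIDE_BITS.items() if self.wall_mask & b)


@dataclass
class Cell:
    """A polygonal cell: an ordered (counter-clockwise) vertex-id ring."""

    id: int
    vertex_ids: list[int] = field(default_factory=list)

    @property
    def n_sides(self) -> int:
        return len(self.vertex_ids)


def snap_to_wall(vertex: Vertex, geom: ChannelGeometry) -> np.ndarray:
    """Project a wall-flagged vertex back onto its wall curve.

    Top/bottom flags replace ``y`` by the signed half-width at the current
    ``x``; inlet/outlet flags clamp ``x`` to the channel end.  Interior
    vertices are returned unchanged.
    """
    p = np.array(vertex.position, dtype=float)
    m = vertex.wall_mask
    if m & WALL_INLET:
        p[0] = geom.x_min
    if m & WALL_OUTLET:
        p[0] = geom.x_max
    p[0] = min(max(p[0], geom.x_min), geom.x_max)
    if m & WALL_TOP:
        p[1] = geom.half_width(p[0])
    elif m & WALL_BOTTOM:
        p[1] = -geom.half_width(p[0])
    return p


class TissueMesh:
    """Conformal mesh of polygonal cells sharing vertices and edges.

    Vertex positions live in one growing ``(n, 2)`` array (vertex ids are
    row indices and are never reused), which the mechanics kernels operate
    on directly.  Topology (the cell rings) lives in :class:`Cell` objects;
    any edit must go through the mesh so derived caches are invalidated.
    """

    def __init__(self):
        self._pos = np.zeros((64, 2), dtype=float)
        self._mask = np.zeros(64, dtype=np.uint8)
        self._nv = 0
        self.cells: dict[int, Cell] = {}
        self._next_cell_id = 0
        self.topology_version = 0
        self._edge_cache = None
        self._edge_cache_version = -1

    # -- vertices ----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self._nv

    @property
    def positions(self) -> np.ndarray:
        """Writable ``(n_vertices, 2)`` view of all vertex positions."""
        return self._pos[: self._nv]

    @property
    def wall_mask(self) -> np.ndarray:
        return self._mask[: self._nv]

    def add_vertex(self, position, wall_mask: int = WALL_NONE) -> int:
        if self._nv == self._pos.shape[0]:
            self._pos = np.resize(self._pos, (2 * self._nv, 2))
            self._mask = np.resize(self._mask, 2 * self._nv)
        vid = self._nv
        self._pos[vid] = position
        self._mask[vid] = wall_mask
        self._nv += 1
        return vid

    def vertex(self, vid: int) -> Vertex:
        return Vertex(vid, self._pos[vid], int(self._mask[vid]))

    # -- cells -------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def add_cell(self, vertex_ids) -> int:
        ids = [int(v) for v in vertex_ids]
        if len(ids) < 3:
            raise InvalidPolygonError("a cell needs at least 3 vertices")
        if polygon_area(self.positions[ids]) < 0:
            ids.reverse()
        cid = self._next_cell_id
        self._next_cell_id += 1
        self.cells[cid] = Cell(cid, ids)
        self._bump()
        return cid

    def remove_cell(self, cid: int) -> None:
        del self.cells[cid]
        self._bump()

    def _bump(self) -> None:
        self.topology_version += 1

    # -- derived geometry ---------------------------------------------------
    def cell_points(self, cid: int) -> np.ndarray:
        return self.positions[self.cells[cid].vertex_ids]

    def cell_area(self, cid: int) -> float:
        return polygon_area(self.cell_points(cid))

    def cell_perimeter(self, cid: int) -> float:
        return polygon_perimeter(self.cell_points(cid))

    def cell_centroid(self, cid: int) -> np.ndarray:
        return polygon_centroid(self.cell_points(cid))

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells)

    # -- edges --------------------------------------------------------------
    def edge_map(self) -> dict[tuple[int, int], list[int]]:
        """Map unordered vertex-id pair -> incident cell ids (cached)."""
        if self._edge_cache_version != self.topology_version:
            edges: dict[tuple[int, int], list[int]] = {}
            for cid, cell in self.cells.items():
                ids = cell.vertex_ids
                n = len(ids)
                for i in range(n):
                    a, b = ids[i], ids[(i + 1) % n]
                    key = (a, b) if a < b else (b, a)
                    edges.setdefault(key, []).append(cid)
            self._edge_cache = edges
            self._edge_cache_version = self.topology_version
        return self._edge_cache

    def vertex_cell_count(self) -> np.ndarray:
        """Number of incident cells per vertex id."""
        from itertools import chain

        ids = np.fromiter(
            chain.from_iterable(c.vertex_ids for c in self.cells.values()),
            dtype=np.int64,
        )
        return np.bincount(ids, minlength=self._nv)

    # -- validation ---------------------------------------------------------
    def validate_fast(self) -> None:
        """Cheap conformity check used inside the step loop.

        Verifies ring sizes and edge incidence counts from the compiled
        arrays; the full :meth:`validate` (orientation, ring duplicates,
        coincident vertices) runs at output times.  Transiently inverted
        slivers are left to the orientation repair in the step loop.
        """
        from ._flat import compile_mesh

        flat = compile_mesh(self)
        if flat.n_cells == 0:
            return
        if flat.cell_len.min() < 3:
            raise MeshConformityError("cell with < 3 vertices")
        if flat.edge_count.max(initial=0) > 2:
            raise MeshConformityError("edge incident to > 2 cells")

    def validate(self, check_overlap: bool = False) -> None:
        """Assert mesh conformity; raise :class:`MeshConformityError` if broken.

        Checks: every edge incident to one or two cells, every cell has
        at least 3 vertices, positive (counter-clockwise) area, and no two
        distinct vertices closer than 1e-9.  With ``check_overlap`` the
        cell interiors are also tested for pairwise disjointness (slow;
        meant for small fixtures).
        """
        for cid, cell in self.cells.items():
            if len(cell.vertex_ids) < 3:
                raise MeshConformityError(f"cell {cid} has < 3 vertices")
            if len(set(cell.vertex_ids)) != len(cell.vertex_ids):
                raise MeshConformityError(f"cell {cid} repeats a vertex")
            if self.cell_area(cid) <= 0:
                raise MeshConformityError(f"cell {cid} is not counter-clockwise")
        for (a, b), cids in self.edge_map().items():
            if not 1 <= len(cids) <= 2:
                raise MeshConformityError(
                    f"edge ({a},{b}) incident to {len(cids)} cells"
                )
        used = sorted({v for c in self.cells.values() for v in c.vertex_ids})
        if used:
            pts = self.positions[used]
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            srt = pts[order]
            close = np.linalg.norm(np.diff(srt, axis=0), axis=1) < 1e-9
            for i in np.nonzero(close)[0]:
                va = used[int(order[i])]
                vb = used[int(order[i + 1])]
                # vertices pinned into a channel corner (two wall bits set)
                # legitimately coincide there
                if (bin(int(self.wall_mask[va])).count("1") >= 2
                        and bin(int(self.wall_mask[vb])).count("1") >= 2):
                    continue
                raise MeshConformityError(
                    f"distinct vertices coincide near {srt[i]}"
                )
        if check_overlap:
            self._check_overlap()

    def _check_overlap(self) -> None:
        try:
            from shapely.geometry import Polygon
        except ImportError:  # pragma: no cover
            return
        polys = {c: Polygon(self.cell_points(c)) for c in self.cells}
        ids = sorted(polys)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                inter = polys[a].intersection(polys[b]).area
                if inter > 1e-9 * min(polys[a].area, polys[b].area):
                    raise MeshConformityError(f"cells {a} and {b} overlap")

    def repair_orientation(self) -> int:
        """Re-orient any clockwise cell; returns how many were flipped."""
        flipped = 0
        for cell in self.cells.values():
            if polygon_area(self.positions[cell.vertex_ids]) < 0:
                cell.vertex_ids.reverse()
                flipped += 1
        if flipped:
            self._bump()
        return flipped
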