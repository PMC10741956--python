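"""Stochastic cell division and the T1 intercalation topology edit.

Division of cell *i* is attempted with probability

    P_i = P0 H(A_i - m A0) T(tau) q^(n_i - 6),

so only cells that have regrown past the size gate ``m A0`` divide, cells
with many sides divide more often (for ``q > 1``), and the fluid shear
stress modulates the rate through the resonant response

    T(tau) = 1 / [ (1 - tau^2)^2 + delta tau^2 ],

which equals 1 in a liquid at rest, peaks at ``tau_res = sqrt(1 - delta/2)``
with value ``1 / [delta (1 - delta/4)]`` and vanishes at high stress.

A division cuts the mother from the midpoint of its longest side to the
midpoint of the opposite side; an intercalation replaces an interior edge
shorter than ``l0`` by a perpendicular edge 5 % longer, swapping which
cell pairs are adjacent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    TissueMesh,
    WALL_TOP,
    WALL_BOTTOM,
    polygon_centroid,
)

__all__ = [
    "EventParams",
    "shear_response",
    "resonant_stress",
    "division_probability",
    "divide_cell",
    "find_intercalation_candidates",
    "perform_t1",
    "collapse_short_edges",
]

log = logging.getLogger(__name__)

#: Division trials per cell per unit time.  The printed model gives the
#: per-trial probability P0 but no time base; this rate is the model
#: closure, calibrated once against the straight-channel population
#: magnitude of the uniform-growth scenario (see docs/methods.md).
DEFAULT_TRIALS_PER_UNIT_TIME = 137.0


@dataclass(frozen=True)
class EventParams:
    """Event constants (reference-parameter set).

    P0 : base division probability per trial (5e-5)
    q : side-count factor (1.4); heptagons divide more often than pentagons
    m : size gate as a fraction of the reference area (0.7)
    delta : width of the shear-stress resonance (0.04), 0 < delta < 2
    l0 : critical edge length triggering intercalation (0.15)
    extrusion_factor : elongation of the post-T1 edge (1.05)
    trials_per_unit_time : division-trial rate per cell
    """

    P0: float = 5e-5
    q: float = 1.4
    m: float = 0.7
    delta: float = 0.04
    l0: float = 0.15
    extrusion_factor: float = 1.05
    trials_per_unit_time: float = DEFAULT_TRIALS_PER_UNIT_TIME
    #: edges that cannot intercalate (free-front or wall edges, blocked
    #: junctions) are collapsed by a vertex merge below this length; also
    #: the length floor of the Courant rule in the driver loop.
    l_merge: float = 0.05
    #: refractory time after a T1 during which the flipped edge may not
    #: flip again; prevents ping-pong oscillations of a compressed edge
    #: around the critical length.
    t1_cooldown: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.m < 1.0):
            raise ValueError("m must lie in (0, 1)")
        if not self.q > 0:
            raise ValueError("q must be positive")
        if not (0.0 < self.delta < 2.0):
            raise ValueError("delta must lie in (0, 2)")
        if not self.l0 > 0:
            raise ValueError("l0 must be positive")

    def with_(self, **kw) -> "EventParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# shear response
# ---------------------------------------------------------------------------

def shear_response(tau, delta: float):
    """Resonant division-rate factor ``T(tau) = 1/[(1-tau^2)^2 + delta tau^2]``."""
    if delta <= 0:
        raise ValueError("delta must be positive (T diverges at tau=1)")
    t2 = np.square(np.asarray(tau, dtype=float))
    out = 1.0 / ((1.0 - t2) ** 2 + delta * t2)
    return float(out) if out.ndim == 0 else out


def resonant_stress(delta: float) -> float:
    """Stress maximizing :func:`shear_response`: ``sqrt(1 - delta/2)``."""
    if not (0.0 < delta < 2.0):
        raise ValueError("an interior maximum requires 0 < delta < 2")
    return math.sqrt(1.0 - delta / 2.0)


def division_probability(n_sides: int, area: float, tau: float,
                         params: EventParams,
                         A0: float) -> float:
    """Per-trial division probability of one cell (H(0) = 0 convention)."""
    if area <= params.m * A0:
        return 0.0
    return params.P0 * shear_response(tau, params.delta) * params.q ** (n_sides - 6)


# ---------------------------------------------------------------------------
# division
# ---------------------------------------------------------------------------

def _edge_sort_key(mesh: TissueMesh, a: int, b: int):
    return (min(a, b), max(a, b))


def _longest_edge(mesh: TissueMesh, ids: list[int]) -> int:
    pos = mesh.positions
    n = len(ids)
    lengths = [
        float(np.linalg.norm(pos[ids[(i + 1) % n]] - pos[ids[i]]))
        for i in range(n)
    ]
    best = max(lengths)
    tied = [i for i, l in enumerate(lengths) if l == best]
    # deterministic tie-break on the sorted vertex-id pair
    return min(tied, key=lambda i: _edge_sort_key(mesh, ids[i], ids[(i + 1) % n]))


def divide_cell(mesh: TissueMesh, cell_id: int, rng=None) -> tuple[int, int] | None:
    """Bisect a cell across its longest side; returns the daughter ids.

    The cut runs from the midpoint of the longest side to the midpoint of
    the opposite side (the farther of the two candidates when the side
    count is odd, ties broken by vertex-id order).  The two midpoints
    become new shared vertices; neighbours incident to the cut sides gain
    the corresponding midpoint so the mesh stays conformal.  Daughter
    areas sum exactly to the mother area.  Returns ``None`` (and logs) if
    the cut would create a polygon with fewer than three vertices.
    """
    cell = mesh.cells[cell_id]
    ids = cell.vertex_ids
    n = len(ids)
    pos = mesh.positions

    i1 = _longest_edge(mesh, ids)
    if n % 2 == 0:
        i2 = (i1 + n // 2) % n
    else:
        c1, c2 = (i1 + n // 2) % n, (i1 + (n + 1) // 2) % n
        l1 = float(np.linalg.norm(pos[ids[(c1 + 1) % n]] - pos[ids[c1]]))
        l2 = float(np.linalg.norm(pos[ids[(c2 + 1) % n]] - pos[ids[c2]]))
        if l1 > l2:
            i2 = c1
        elif l2 > l1:
            i2 = c2
        else:
            i2 = min(c1, c2, key=lambda i: _edge_sort_key(mesh, ids[i], ids[(i + 1) % n]))

    def _walk(start, stop):
        out = []
        j = start
        while True:
            out.append(ids[j])
            if j == stop:
                return out
            j = (j + 1) % n

    ring_a = _walk((i1 + 1) % n, i2)
    ring_b = _walk((i2 + 1) % n, i1)
    if len(ring_a) + 2 < 3 or len(ring_b) + 2 < 3:
        log.info("division of cell %d skipped: degenerate daughter", cell_id)
        return None

    edge_map = mesh.edge_map()

    def _cut_edge(i):
        a, b = ids[i], ids[(i + 1) % n]
        mid = 0.5 * (pos[a] + pos[b])
        mask = int(mesh.wall_mask[a]) & int(mesh.wall_mask[b])
        if not (mask & (WALL_TOP | WALL_BOTTOM)):
            mask &= ~0  # inlet/outlet bits may survive only if common
        vid = mesh.add_vertex(mid, mask)
        key = (a, b) if a < b else (b, a)
        neighbours = [c for c in edge_map[key] if c != cell_id]
        for ncid in neighbours:
            ring = mesh.cells[ncid].vertex_ids
            m = len(ring)
            for p in range(m):
                if ring[p] == b and ring[(p + 1) % m] == a:
                    ring.insert(p + 1, vid)
                    break
            else:  # pragma: no cover - conformity breach upstream
                raise RuntimeError("cut edge missing from neighbour ring")
        return vid

    m1 = _cut_edge(i1)
    m2 = _cut_edge(i2)

    mesh.remove_cell(cell_id)
    d1 = mesh.add_cell([m1, *ring_a, m2])
    d2 = mesh.add_cell([m2, *ring_b, m1])
    return d1, d2


# ---------------------------------------------------------------------------
# intercalation (T1)
# ---------------------------------------------------------------------------

def find_intercalation_candidates(mesh: TissueMesh, l0: float) -> list[tuple[int, int]]:
    """Interior edges shorter than ``l0`` that admit a T1 swap.

    An endpoint qualifies if it is an interior three-fold junction, or a
    wall vertex shared by exactly two cells (the wall plays the role of
    the fourth cell).  Edges of length exactly ``l0`` are excluded
    (Heaviside ``H(0) = 0``); free-front edges (one incident cell) never
    qualify.
    """
    from ._flat import compile_mesh

    flat = compile_mesh(mesh)
    pos = mesh.positions
    d = pos[flat.edge_b] - pos[flat.edge_a]
    lengths = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
    short = (lengths < l0) & (flat.edge_count == 2)
    if not short.any():
        return []
    counts = np.bincount(flat.corner_vert, minlength=mesh.n_vertices)
    on_wall = (mesh.wall_mask & (WALL_TOP | WALL_BOTTOM)) != 0
    a = flat.edge_a[short]
    b = flat.edge_b[short]
    ok_a = (counts[a] == 3) & ~on_wall[a]
    ok_b = (counts[b] == 3) & ~on_wall[b]
    wall_ok_a = on_wall[a] & (counts[a] == 2)
    wall_ok_b = on_wall[b] & (counts[b] == 2)
    good = (ok_a | wall_ok_a) & (ok_b | wall_ok_b) & (ok_a | ok_b)
    if not good.any():
        return []
    em = mesh.edge_map()
    out = []
    for va, vb in zip(a[good], b[good]):
        cids = em[(int(va), int(vb))]
        if all(len(mesh.cells[c].vertex_ids) >= 4 for c in cids):
            out.append((int(va), int(vb)))
    out.sort()
    return out


def collapse_short_edges(mesh: TissueMesh, threshold: float,
                         geom=None) -> int:
    """Merge the endpoints of edges shorter than ``threshold``.

    Intercalation relieves short *interior* edges at ``l0``, but edges on
    the free front or on a wall, and edges whose junction degrees block a
    T1, have no such escape: under compression they shrink indefinitely,
    which would stall the Courant-limited time step.  Collapsing such an
    edge (the merged vertex sits at the old midpoint and inherits the
    union of the wall flags) removes the degenerate side.  A merge that
    would leave any incident cell with fewer than three vertices is
    skipped.  Returns the number of collapsed edges.
    """
    from ._flat import compile_mesh

    merged = 0
    for _ in range(16):  # edge tables refresh after every merge
        pos = mesh.positions
        flat = compile_mesh(mesh)
        d = pos[flat.edge_b] - pos[flat.edge_a]
        lengths = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
        idx = np.nonzero(lengths < threshold)[0]
        if idx.size == 0:
            return merged
        em = mesh.edge_map()
        target = None
        for i in idx:
            a, b = int(flat.edge_a[i]), int(flat.edge_b[i])
            affected = [c for c in mesh.cells.values() if b in c.vertex_ids]
            ok = True
            for c in affected:
                if a in c.vertex_ids:
                    ids = c.vertex_ids
                    ia, ib = ids.index(a), ids.index(b)
                    adjacent = (ia - ib) % len(ids) in (1, len(ids) - 1)
                    if not adjacent or len(ids) - 1 < 3:
                        ok = False
                        break
            if ok:
                # the merge must not over-share any edge: every edge (b,x)
                # turns into (a,x), whose total incidence must stay <= 2
                for (u, v), cids2 in em.items():
                    if b not in (u, v):
                        continue
                    x = v if u == b else u
                    if x == a:
                        continue
                    key_ax = (a, x) if a < x else (x, a)
                    if len(cids2) + len(em.get(key_ax, [])) > 2:
                        ok = False
                        break
            if ok:
                target = (a, b, affected)
                break
        if target is None:
            return merged
        a, b, affected = target
        mesh.positions[a] = 0.5 * (mesh.positions[a] + mesh.positions[b])
        mesh.wall_mask[a] |= mesh.wall_mask[b]
        for c in affected:
            if a in c.vertex_ids:
                c.vertex_ids.remove(b)
            else:
                c.vertex_ids[c.vertex_ids.index(b)] = a
        mesh._bump()
        merged += 1
    return merged


def _third_cell(mesh: TissueMesh, vid: int, exclude: set[int]) -> int | None:
    for cid, cell in mesh.cells.items():
        if cid not in exclude and vid in cell.vertex_ids:
            return cid
    return None


def _wing_neighbour(mesh: TissueMesh, em, ring: list[int], anchor: int,
                    toward_cell: int) -> int | None:
    """Among the two ring neighbours of ``anchor``, the one whose edge with
    ``anchor`` is shared with ``toward_cell`` (pre-edit edge table)."""
    n = len(ring)
    p = ring.index(anchor)
    for w in (ring[(p - 1) % n], ring[(p + 1) % n]):
        key = (anchor, w) if anchor < w else (w, anchor)
        if toward_cell in em.get(key, ()):
            return w
    return None


def _insert_between(ring: list[int], anchor: int, wing: int, new: int) -> None:
    """Insert ``new`` into the ring between adjacent ``anchor`` and ``wing``."""
    n = len(ring)
    p = ring.index(anchor)
    if ring[(p + 1) % n] == wing:
        ring.insert(p + 1, new)
    else:
        ring.insert(p, new)


def perform_t1(mesh: TissueMesh, edge: tuple[int, int],
               extrusion_factor: float = 1.05, geom=None) -> bool:
    """Swap adjacency across a short edge (T1 transition).

    The edge shared by cells *i*, *j* is replaced by an edge between the
    two formerly non-adjacent cells, centred on the old midpoint, rotated
    by 90 degrees and elongated by ``extrusion_factor``.  When one
    endpoint sits on a channel wall shared by only *i* and *j*, the wall
    acts as the fourth neighbour: the new edge lies along the wall and the
    third cell comes into wall contact.  Returns False (no edit) if the
    swap would leave a cell with fewer than three vertices.
    """
    v1, v2 = edge
    key = (v1, v2) if v1 < v2 else (v2, v1)
    cids = mesh.edge_map().get(key)
    if cids is None or len(cids) != 2:
        return False
    ci, cj = cids
    if len(mesh.cells[ci].vertex_ids) < 4 or len(mesh.cells[cj].vertex_ids) < 4:
        return False

    mask = mesh.wall_mask
    counts = mesh.vertex_cell_count()
    wall_bits = WALL_TOP | WALL_BOTTOM

    def _is_wall_endpoint(v):
        return bool(mask[v] & wall_bits) and counts[v] == 2

    # orient so that v1 is the interior three-fold junction
    if _is_wall_endpoint(v1):
        v1, v2 = v2, v1
    ck = _third_cell(mesh, v1, {ci, cj})
    on_wall = _is_wall_endpoint(v2)
    cl = None if on_wall else _third_cell(mesh, v2, {ci, cj})
    if ck is None or (not on_wall and cl is None) or ck == cl:
        return False

    pos = mesh.positions
    p1, p2 = pos[v1].copy(), pos[v2].copy()
    mid = 0.5 * (p1 + p2)
    d = p2 - p1
    ln = float(np.linalg.norm(d))
    if ln < 1e-14:
        return False
    perp = np.array([-d[1], d[0]]) / ln
    half = 0.5 * extrusion_factor * ln
    pa = mid + half * perp
    pb = mid - half * perp

    ci_centroid = polygon_centroid(pos[mesh.cells[ci].vertex_ids])
    # v1 stays with cell i, v2 with cell j: give v1 the endpoint nearer i
    if np.linalg.norm(pa - ci_centroid) <= np.linalg.norm(pb - ci_centroid):
        new1, new2 = pa, pb
    else:
        new1, new2 = pb, pa

    # topological wings, resolved on the pre-edit edge table: in cell k the
    # new vertex v2 sits between v1 and k's edge shared with j (and v1 in
    # cell l between v2 and l's edge shared with i)
    em = mesh.edge_map()
    wing_k = _wing_neighbour(mesh, em, mesh.cells[ck].vertex_ids, v1, cj)
    wing_l = None if on_wall else _wing_neighbour(
        mesh, em, mesh.cells[cl].vertex_ids, v2, ci
    )
    if wing_k is None or (not on_wall and wing_l is None):
        return False

    old_mask2 = int(mask[v2])
    pos[v1] = new1
    pos[v2] = new2

    mesh.cells[ci].vertex_ids.remove(v2)
    mesh.cells[cj].vertex_ids.remove(v1)
    _insert_between(mesh.cells[ck].vertex_ids, v1, wing_k, v2)
    if on_wall:
        # both endpoints of the new edge slide onto the wall curve
        side = old_mask2 & wall_bits
        mask[v1] = int(mask[v1]) | side
        if geom is not None:
            for v in (v1, v2):
                x = min(max(pos[v, 0], geom.x_min), geom.x_max)
                w = geom.half_width(x)
                pos[v] = (x, w if side & WALL_TOP else -w)
    else:
        _insert_between(mesh.cells[cl].vertex_ids, v2, wing_l, v1)
    mesh._bump()
    return True
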