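"""Flattened corner/edge arrays compiled from a :class:`TissueMesh`.

The per-step mechanics runs on contiguous arrays rather than on the cell
objects.  The compiled view is cached on the mesh and rebuilt only after
a topology edit (division or intercalation); vertex positions are shared
with the mesh, never copied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain

import numpy as np

__all__ = ["FlatMesh", "compile_mesh"]


@dataclass
class FlatMesh:
    cell_ids: np.ndarray      # compact cell index -> cell id
    cell_len: np.ndarray      # sides per cell
    corner_cell: np.ndarray   # corner -> compact cell index
    corner_vert: np.ndarray   # corner -> vertex id
    next_vert: np.ndarray     # corner -> vertex id of next corner in ring
    prev_vert: np.ndarray     # corner -> vertex id of previous corner
    edge_a: np.ndarray        # unique edges, smaller vertex id
    edge_b: np.ndarray        # unique edges, larger vertex id
    edge_count: np.ndarray    # incident cells per unique edge
    n_vertices: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def compile_mesh(mesh) -> FlatMesh:
    """Build (or fetch the cached) flat view of ``mesh``."""
    cached = getattr(mesh, "_flat_cache", None)
    if cached is not None and cached[0] == mesh.topology_version:
        return cached[1]

    cids = sorted(mesh.cells)
    rings = [mesh.cells[c].vertex_ids for c in cids]
    lens = np.fromiter((len(r) for r in rings), dtype=np.int64, count=len(rings))
    total = int(lens.sum())
    cv = np.fromiter(chain.from_iterable(rings), dtype=np.int64, count=total)
    cc = np.repeat(np.arange(len(cids), dtype=np.int64), lens)
    start = np.concatenate(([0], np.cumsum(lens)[:-1])) if len(lens) else np.zeros(0, np.int64)

    idx = np.arange(total, dtype=np.int64)
    local = idx - start[cc]
    nxt = start[cc] + (local + 1) % lens[cc]
    prv = start[cc] + (local - 1) % lens[cc]

    a = np.minimum(cv, cv[nxt])
    b = np.maximum(cv, cv[nxt])
    key = a * np.int64(mesh.n_vertices + 1) + b
    uniq, counts = np.unique(key, return_counts=True)
    edge_a = uniq // np.int64(mesh.n_vertices + 1)
    edge_b = uniq % np.int64(mesh.n_vertices + 1)

    flat = FlatMesh(
        cell_ids=np.asarray(cids, dtype=np.int64),
        cell_len=lens,
        corner_cell=cc,
        corner_vert=cv,
        next_vert=cv[nxt],
        prev_vert=cv[prv],
        edge_a=edge_a,
        edge_b=edge_b,
        edge_count=counts,
        n_vertices=mesh.n_vertices,
    )
    mesh._flat_cache = (mesh.topology_version, flat)
    return flat
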