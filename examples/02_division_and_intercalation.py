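"""The two topology events: mitotic division and the T1 swap.

Divides a single hexagonal cell (longest-side bisection) and then flips
a short edge in a four-cell fixture, printing how side counts, areas and
adjacency change.
"""

import numpy as np

from porevertex import ChannelGeometry, divide_cell, init_single_cell, perform_t1
from porevertex.geometry import TissueMesh

# --- division: a hexagon splits into two pentagons of equal area -------
mesh = init_single_cell(ChannelGeometry(), a=2.0)
print("mother: sides =", mesh.cells[0].n_sides, " area =", round(mesh.cell_area(0), 5))
d1, d2 = divide_cell(mesh, 0)
print("daughters: sides =", [mesh.cells[c].n_sides for c in (d1, d2)],
      " areas =", [round(mesh.cell_area(c), 5) for c in (d1, d2)])
# The cut runs between the midpoints of the longest side and the side
# opposite to it; the daughter areas sum exactly to the mother area.

# --- T1: a short edge flips and swaps which cells touch ----------------
m = TissueMesh()
pts = {"a": (-1, 1), "b": (1, 1), "c": (1, -1), "d": (-1, -1),
       "e": (-1.5, 0), "f": (1.5, 0), "g": (0, 1.5), "h": (0, -1.5),
       "v1": (0, 0.05), "v2": (0, -0.05)}
ids = {k: m.add_vertex(p) for k, p in pts.items()}
left = m.add_cell([ids["e"], ids["d"], ids["v2"], ids["v1"], ids["a"]])
right = m.add_cell([ids["f"], ids["b"], ids["v1"], ids["v2"], ids["c"]])
top = m.add_cell([ids["v1"], ids["b"], ids["g"], ids["a"]])
bottom = m.add_cell([ids["v2"], ids["d"], ids["h"], ids["c"]])

old = np.linalg.norm(m.positions[ids["v1"]] - m.positions[ids["v2"]])
perform_t1(m, (ids["v1"], ids["v2"]), extrusion_factor=1.05)
new = np.linalg.norm(m.positions[ids["v1"]] - m.positions[ids["v2"]])
print(f"\nT1: edge length {old:.3f} -> {new:.3f} (rotated 90 deg, 5% longer)")
print("new edge now shared by cells", m.edge_map()[tuple(sorted((ids['v1'], ids['v2'])))],
      "(top/bottom), left and right cells have separated")
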