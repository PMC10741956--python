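import math

import numpy as np
import pytest

from porevertex.geometry import ChannelGeometry, TissueMesh
from porevertex.mechanics import MechParams
from porevertex.events import EventParams
from porevertex.simulation import init_hex_patch


@pytest.fixture
def mech_params() -> MechParams:
    """Reference mechanical constants for a cell of diameter 2."""
    return MechParams.from_cell_diameter(2.0)


@pytest.fixture
def event_params() -> EventParams:
    return EventParams()


@pytest.fixture
def wavy_geom() -> ChannelGeometry:
    """The wavy-pore geometry used by the growth scenarios."""
    return ChannelGeometry(h=4.5, epsilon=0.2, wavenumber=1.0 / 6.0,
                           phase=-math.pi / 2.0, x_min=0.0, x_max=120.0)


@pytest.fixture
def patch3() -> TissueMesh:
    return init_hex_patch(3, 3)


@pytest.fixture
def pinwheel():
    """Four cells around a short central edge: the canonical T1 fixture.

    Returns (mesh, ids, cell ids) where the central edge (v1, v2) of
    length 0.1 is shared by the left and right cells and each endpoint is
    a three-fold junction.
    """
    m = TissueMesh()
    pts = {
        "a": (-1, 1), "b": (1, 1), "c": (1, -1), "d": (-1, -1),
        "e": (-1.5, 0), "f": (1.5, 0), "g": (0, 1.5), "h": (0, -1.5),
        "v1": (0, 0.05), "v2": (0, -0.05),
    }
    ids = {k: m.add_vertex(p) for k, p in pts.items()}
    cells = {
        "left": m.add_cell([ids["e"], ids["d"], ids["v2"], ids["v1"], ids["a"]]),
        "right": m.add_cell([ids["f"], ids["b"], ids["v1"], ids["v2"], ids["c"]]),
        "top": m.add_cell([ids["v1"], ids["b"], ids["g"], ids["a"]]),
        "bottom": m.add_cell([ids["v2"], ids["d"], ids["h"], ids["c"]]),
    }
    m.validate()
    return m, ids, cells


def random_convex_polygon(rng: np.random.Generator, n: int) -> np.ndarray:
    """Convex n-gon: distinct points on a circle (convex by construction)
    pushed through a random affine map, which preserves convexity."""
    while True:
        th = np.sort(rng.uniform(0, 2 * np.pi, n))
        if np.diff(np.concatenate([th, [th[0] + 2 * np.pi]])).min() > 0.05:
            break
    pts = np.column_stack([np.cos(th), np.sin(th)])
    stretch = np.diag(rng.uniform(0.7, 1.5, 2))
    a = rng.uniform(0, np.pi)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ stretch @ rot.T
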