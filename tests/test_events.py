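import math

import numpy as np
import pytest

from porevertex.events import (
    EventParams,
    divide_cell,
    division_probability,
    find_intercalation_candidates,
    perform_t1,
    resonant_stress,
    shear_response,
)
from porevertex.geometry import ChannelGeometry, TissueMesh, polygon_area
from porevertex.simulation import init_hex_patch, init_single_cell
from conftest import random_convex_polygon

A0 = 3.0 * math.sqrt(3.0) / 2.0
DELTA = 0.04


class TestShearResponse:
    def test_rest_liquid_gives_unit_factor(self):
        assert shear_response(0.0, DELTA) == 1.0

    def test_high_stress_suppresses_division(self):
        assert shear_response(10.0, DELTA) == pytest.approx(1.0199e-4, rel=1e-3)
        assert shear_response(1e3, DELTA) < 1e-11

    def test_resonant_value(self):
        """T at the resonance equals 1/[delta (1 - delta/4)]."""
        t = shear_response(resonant_stress(DELTA), DELTA)
        assert t == pytest.approx(1.0 / (DELTA * (1.0 - DELTA / 4.0)), rel=1e-12)
        assert t == pytest.approx(25.2525, rel=1e-4)

    def test_resonant_stress_value(self):
        assert resonant_stress(DELTA) == pytest.approx(math.sqrt(0.98), rel=1e-12)
        assert resonant_stress(DELTA) == pytest.approx(0.98995, rel=1e-4)
        assert resonant_stress(1.999999) == pytest.approx(0.0, abs=1e-2)

    def test_resonance_is_global_maximum(self):
        """Grid + golden-section oracle confirms the argmax of T."""
        from scipy.optimize import minimize_scalar

        grid = np.linspace(0.0, 5.0, 20001)
        t_grid = shear_response(grid, DELTA)
        tau_star = resonant_stress(DELTA)
        assert np.all(shear_response(tau_star, DELTA) >= t_grid)
        res = minimize_scalar(lambda t: -shear_response(t, DELTA),
                              bounds=(0.5, 1.5), method="bounded")
        assert res.x == pytest.approx(tau_star, rel=1e-6)

    def test_monotone_decay_past_resonance(self):
        taus = np.linspace(resonant_stress(DELTA), 50.0, 500)
        vals = shear_response(taus, DELTA)
        assert np.all(np.diff(vals) < 0)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            shear_response(1.0, 0.0)
        with pytest.raises(ValueError):
            resonant_stress(2.0)


class TestDivisionProbability:
    def test_reference_hexagon_rate(self, event_params):
        p = division_probability(6, 0.8 * A0, 0.0, event_params, A0)
        assert p == pytest.approx(5e-5, rel=1e-12)

    def test_size_gate_blocks_small_cells(self, event_params):
        assert division_probability(6, 0.5 * A0, 0.0, event_params, A0) == 0.0
        # H(0) = 0: exactly at the gate still blocked
        assert division_probability(6, 0.7 * A0, 0.0, event_params, A0) == 0.0

    def test_heptagon_divides_more_often(self, event_params):
        p = division_probability(7, 0.8 * A0, 0.0, event_params, A0)
        assert p == pytest.approx(7e-5, rel=1e-12)

    def test_monotone_in_side_count(self, event_params):
        probs = [division_probability(n, A0, 0.0, event_params, A0)
                 for n in range(3, 10)]
        assert np.all(np.diff(probs) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EventParams(m=1.5)
        with pytest.raises(ValueError):
            EventParams(delta=2.5)


class TestDivision:
    def test_square_bisects_into_equal_halves(self):
        m = TissueMesh()
        m.add_cell([m.add_vertex(p) for p in [(0, 0), (1, 0), (1, 1), (0, 1)]])
        d1, d2 = divide_cell(m, 0)
        assert m.cell_area(d1) == pytest.approx(0.5)
        assert m.cell_area(d2) == pytest.approx(0.5)
        m.validate(check_overlap=True)

    def test_hexagon_splits_into_two_pentagons(self):
        m = init_single_cell(ChannelGeometry(), 2.0)
        d1, d2 = divide_cell(m, 0)
        assert m.cells[d1].n_sides == 5
        assert m.cells[d2].n_sides == 5
        m.validate(check_overlap=True)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8, 9])
    @pytest.mark.parametrize("seed", range(17))
    def test_daughters_partition_mother_exactly(self, n, seed):
        rng = np.random.default_rng(100 * n + seed)
        pts = random_convex_polygon(rng, n)
        if polygon_area(pts) < 0:
            pts = pts[::-1]
        m = TissueMesh()
        m.add_cell([m.add_vertex(p) for p in pts])
        mother_area = m.cell_area(0)
        d1, d2 = divide_cell(m, 0)
        assert m.cell_area(d1) + m.cell_area(d2) == pytest.approx(
            mother_area, rel=1e-12
        )
        m.validate(check_overlap=True)

    def test_neighbour_gains_cut_midpoint(self, patch3):
        """Dividing an interior cell inserts midpoints into its neighbours."""
        # central cell of the 3x3 honeycomb
        cid = 4
        neigh_sides = {c: patch3.cells[c].n_sides for c in patch3.cells}
        divide_cell(patch3, cid)
        patch3.validate(check_overlap=True)
        gained = [
            c for c, cell in patch3.cells.items()
            if c in neigh_sides and cell.n_sides == neigh_sides[c] + 1
        ]
        assert len(gained) == 2  # one neighbour per cut side
        assert patch3.n_cells == 10

    def test_cell_count_grows_by_one(self, patch3):
        n0 = patch3.n_cells
        divide_cell(patch3, 0)
        assert patch3.n_cells == n0 + 1


class TestIntercalation:
    def test_candidate_length_gate(self, pinwheel):
        m, ids, _ = pinwheel
        # central edge has length 0.1
        assert find_intercalation_candidates(m, 0.15) == [(ids["v1"], ids["v2"])]
        # H(0)=0: an edge of length exactly l0 is not a candidate
        assert find_intercalation_candidates(m, 0.1) == []
        assert find_intercalation_candidates(m, 0.05) == []

    def test_boundary_edges_never_candidates(self, pinwheel):
        m, ids, _ = pinwheel
        # shrink a free-front edge below l0: still not a candidate
        m.positions[ids["g"]] = (0.02, 1.06)
        m.positions[ids["a"]] = (-0.02, 1.02)
        cands = find_intercalation_candidates(m, 0.15)
        assert (min(ids["g"], ids["a"]), max(ids["g"], ids["a"])) not in cands

    def test_t1_swaps_adjacency(self, pinwheel):
        m, ids, cells = pinwheel
        area0 = m.total_area()
        cell_area = m.cell_area(cells["left"])
        assert perform_t1(m, (ids["v1"], ids["v2"]), 1.05)
        m.validate(check_overlap=True)
        em = m.edge_map()
        key = (min(ids["v1"], ids["v2"]), max(ids["v1"], ids["v2"]))
        assert sorted(em[key]) == sorted([cells["top"], cells["bottom"]])
        # previously adjacent pair no longer shares an edge
        shared = [
            k for k, v in em.items()
            if sorted(v) == sorted([cells["left"], cells["right"]])
        ]
        assert shared == []
        # new edge: rotated 90 degrees and 5% longer than the old one
        d = m.positions[ids["v1"]] - m.positions[ids["v2"]]
        assert np.linalg.norm(d) == pytest.approx(0.105, rel=1e-12)
        assert abs(d[1]) < 1e-12  # old edge was vertical
        # area change bounded by 1% of a cell area
        assert abs(m.total_area() - area0) < 0.01 * cell_area

    def test_t1_updates_side_counts(self, pinwheel):
        m, ids, cells = pinwheel
        perform_t1(m, (ids["v1"], ids["v2"]), 1.05)
        assert m.cells[cells["left"]].n_sides == 4
        assert m.cells[cells["right"]].n_sides == 4
        assert m.cells[cells["top"]].n_sides == 5
        assert m.cells[cells["bottom"]].n_sides == 5

    def test_t1_skipped_for_triangles(self, pinwheel):
        m, ids, cells = pinwheel
        # shrink the left cell to a triangle: T1 would make it degenerate
        m.cells[cells["left"]].vertex_ids.remove(ids["e"])
        m.cells[cells["left"]].vertex_ids.remove(ids["a"])
        m._bump()
        assert not perform_t1(m, (ids["v1"], ids["v2"]), 1.05)
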