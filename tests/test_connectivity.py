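"""Resistance transform, node placement, circuit solves, change classes."""

import numpy as np
import numpy.testing as npt
import pytest
from shapely.geometry import Point, box

from nicheshift import (
    GridSpec,
    classify_connectivity_change,
    sample_buffer_nodes,
    solve_pairwise_current,
    suitability_to_resistance,
)
from nicheshift.connectivity import CurrentMap, NodeSet, ResistanceSurface
from ._oracles import dense_grid_network, effective_resistance_dense


def surface_of(arr, cell_size=1000.0):
    arr = np.asarray(arr, dtype=float)
    return ResistanceSurface(
        values=arr, grid=GridSpec(arr.shape[0], arr.shape[1], cell_size), shape_c=8.0
    )


def nodes_at(cells):
    return NodeSet(points=np.zeros((len(cells), 2)), cells=list(cells), seed=0, buffer_km=0.0)


class TestResistanceTransform:
    def test_endpoints_exact(self):
        for c in (0.5, 2.0, 8.0, 25.0):
            r = suitability_to_resistance(np.array([[0.0, 1.0]]), c, GridSpec(1, 2, 1.0))
            npt.assert_allclose(r.values, [[100.0, 1.0]])

    def test_midpoint_formula_value(self):
        r = suitability_to_resistance(np.array([[0.5]]), 8.0, GridSpec(1, 1, 1.0))
        expected = 100.0 - 99.0 * (1 - np.exp(-4.0)) / (1 - np.exp(-8.0))
        npt.assert_allclose(r.values[0, 0], expected, atol=1e-9)
        npt.assert_allclose(r.values[0, 0], 2.7806, atol=1e-4)

    def test_strictly_decreasing_in_suitability(self):
        s = np.linspace(0, 1, 101).reshape(1, -1)
        r = suitability_to_resistance(s, 8.0, GridSpec(1, 101, 1.0))
        assert (np.diff(r.values[0]) < 0).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="c must be"):
            suitability_to_resistance(np.array([[0.5]]), -1.0, GridSpec(1, 1, 1.0))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            suitability_to_resistance(np.array([[1.5]]), 8.0, GridSpec(1, 1, 1.0))

    def test_nodata_propagates(self):
        r = suitability_to_resistance(np.array([[np.nan, 0.5]]), 8.0, GridSpec(1, 2, 1.0))
        assert np.isnan(r.values[0, 0]) and not np.isnan(r.values[0, 1])


class TestBufferNodes:
    def test_defaults_and_determinism(self):
        grid = GridSpec(100, 100, 1000.0)
        poly = box(40_000, 40_000, 60_000, 60_000)
        a = sample_buffer_nodes(poly, grid, buffer_km=10.0, n_nodes=18, seed=4)
        b = sample_buffer_nodes(poly, grid, buffer_km=10.0, n_nodes=18, seed=4)
        assert len(a.cells) == 18
        npt.assert_array_equal(a.points, b.points)

    def test_nodes_on_buffer_perimeter(self):
        grid = GridSpec(100, 100, 1000.0)
        poly = box(40_000, 40_000, 60_000, 60_000)
        ns = sample_buffer_nodes(poly, grid, buffer_km=10.0, n_nodes=10, seed=1)
        ring = poly.buffer(10_000.0).exterior
        for x, y in ns.points:
            assert ring.distance(Point(x, y)) < grid.cell_size

    def test_nodes_outside_range_polygon(self):
        grid = GridSpec(100, 100, 1000.0)
        poly = box(40_000, 40_000, 60_000, 60_000)
        ns = sample_buffer_nodes(poly, grid, buffer_km=10.0, n_nodes=10, seed=1)
        for x, y in ns.points:
            assert not poly.contains(Point(x, y))

    def test_oversized_buffer_rejected_with_instruction(self):
        grid = GridSpec(50, 50, 1000.0)
        poly = box(20_000, 20_000, 30_000, 30_000)
        with pytest.raises(ValueError, match="reduce buffer_km"):
            sample_buffer_nodes(poly, grid, buffer_km=500.0, n_nodes=5, seed=0)


class TestCircuitSolve:
    def test_series_chain_by_kirchhoff_hand_solution(self):
        cm = solve_pairwise_current(surface_of(np.ones((1, 3))), nodes_at([(0, 0), (0, 2)]))
        npt.assert_allclose(cm.values, [[1.0, 1.0, 1.0]], atol=1e-10)
        npt.assert_allclose(cm.effective_resistances[(0, 1)], 2.0, atol=1e-10)

    def test_parallel_paths_split_half(self):
        # ring of 8 cells around a nodata centre: two equal paths
        r = np.ones((3, 3))
        r[1, 1] = np.nan
        cm = solve_pairwise_current(
            surface_of(r), nodes_at([(1, 0), (1, 2)]), neighbours=4
        )
        # symmetric: top and bottom mid cells carry half each
        npt.assert_allclose(cm.values[0, 1], 0.5, atol=1e-10)
        npt.assert_allclose(cm.values[2, 1], 0.5, atol=1e-10)

    def test_source_sink_swap_leaves_map_unchanged(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(1, 100, (6, 6))
        a = solve_pairwise_current(surface_of(r), nodes_at([(0, 0), (5, 5)]))
        b = solve_pairwise_current(surface_of(r), nodes_at([(5, 5), (0, 0)]))
        npt.assert_allclose(a.values, b.values, atol=1e-9)

    def test_scale_law_currents_invariant(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(1, 50, (7, 7))
        a = solve_pairwise_current(surface_of(r), nodes_at([(0, 0), (6, 6), (0, 6)]))
        b = solve_pairwise_current(surface_of(3.7 * r), nodes_at([(0, 0), (6, 6), (0, 6)]))
        npt.assert_allclose(a.values, b.values, atol=1e-8)
        for k in a.effective_resistances:
            npt.assert_allclose(
                b.effective_resistances[k], 3.7 * a.effective_resistances[k], rtol=1e-9
            )

    def test_kirchhoff_balance_at_interior_vertices(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(1, 100, (8, 8))
        cells = [(0, 0), (7, 7), (3, 5)]
        cm = solve_pairwise_current(surface_of(r), nodes_at(cells), return_potentials=True)
        L, _ = dense_grid_network(r)
        for (i, j), v_vert in cm.potentials.items():
            v = np.zeros(64)
            v[cm.vertex_index.ravel() >= 0] = v_vert  # all cells valid here
            net = L @ v
            src = cells[i][0] * 8 + cells[i][1]
            snk = cells[j][0] * 8 + cells[j][1]
            expected = np.zeros(64)
            expected[src], expected[snk] = 1.0, -1.0
            npt.assert_allclose(net, expected, atol=1e-8)

    def test_effective_resistance_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            nr, nc = rng.integers(4, 9, 2)
            r = rng.uniform(1, 100, (nr, nc))
            cells = [(0, 0), (nr - 1, nc - 1)]
            cm = solve_pairwise_current(surface_of(r), nodes_at(cells))
            oracle = effective_resistance_dense(r, cells[0], cells[1])
            npt.assert_allclose(cm.effective_resistances[(0, 1)], oracle, rtol=1e-8)

    def test_disconnected_pair_identified(self):
        r = np.ones((3, 5))
        r[:, 2] = np.nan  # vertical barrier
        with pytest.raises(ValueError, match="disconnected"):
            solve_pairwise_current(surface_of(r), nodes_at([(1, 0), (1, 4)]))

    def test_node_on_nodata_rejected(self):
        r = np.ones((3, 3))
        r[1, 1] = np.nan
        with pytest.raises(ValueError, match="nodata"):
            solve_pairwise_current(surface_of(r), nodes_at([(1, 1), (0, 0)]))


class TestConnectivityChange:
    def make_current(self, arr, mask=None):
        arr = np.asarray(arr, dtype=float)
        return CurrentMap(
            values=arr, grid=GridSpec(arr.shape[0], arr.shape[1], 1000.0), range_mask=mask
        )

    def test_identity_maps_three_to_one_ratio(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(20, 20))  # continuous: no percentile ties
        change = classify_connectivity_change(self.make_current(v), self.make_current(v))
        counts = change.category_counts()
        assert counts["high-to-low"] == 0 and counts["low-to-high"] == 0
        assert counts["remained-high"] == 100  # top quartile of 400
        assert counts["remained-low"] == 300

    def test_percentile_computed_within_mask_only(self):
        v = np.zeros((4, 4))
        v[:2] = 100.0  # huge values outside the mask must not shift the cut
        mask = np.zeros((4, 4), dtype=bool)
        mask[2:] = True
        v[2:] = np.arange(8).reshape(2, 4)
        change = classify_connectivity_change(
            self.make_current(v), self.make_current(v), range_mask=mask
        )
        assert change.threshold1 == np.percentile(np.arange(8), 75)
        assert (change.categories[:2] == -1).all()

    def test_single_cell_crossing_upward(self):
        rng = np.random.default_rng(1)
        v1 = rng.uniform(size=(10, 10))
        v2 = v1.copy()
        t2 = np.percentile(v1, 75)
        low_cells = np.argwhere(v1 < np.percentile(v1, 50))
        r, c = low_cells[0]
        v2[r, c] = v1.max() + 1.0
        change = classify_connectivity_change(self.make_current(v1), self.make_current(v2))
        counts = change.category_counts()
        assert counts["low-to-high"] >= 1
        assert change.categories[r, c] == 2

    def test_registration_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_connectivity_change(
                self.make_current(np.zeros((2, 2))), self.make_current(np.zeros((3, 3)))
            )
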