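import numpy as np
import pytest

from epp.density import GRID, density_grid
from epp.dbm import (dip_significant, edge_saddle, merge_insignificant,
                     variance_grid)
from epp.modal import ClusterGraph, Edge, Face
from epp.split import RunConfig, analyze_pair


class TestEdgeSaddle:
    def test_max_along_edge(self):
        d = np.zeros((GRID, GRID))
        pts = np.array([[10, 10], [10, 11], [10, 12]])
        d[10, 10], d[10, 11], d[10, 12] = 0.1, 0.4, 0.2
        pt, val = edge_saddle(d, pts)
        assert pt == (10, 11) and val == 0.4

    def test_single_point_edge(self):
        d = np.zeros((GRID, GRID))
        d[5, 5] = 0.3
        pt, val = edge_saddle(d, np.array([[5, 5]]))
        assert pt == (5, 5) and val == 0.3

    def test_tie_breaks_row_major(self):
        d = np.zeros((GRID, GRID))
        pts = np.array([[20, 7], [4, 9]])
        d[20, 7] = d[4, 9] = 0.5
        assert edge_saddle(d, pts)[0] == (4, 9)

    def test_symmetric_fixture_saddle_on_midline(self, two_gauss_partition):
        grid, labels, cfg = two_gauss_partition
        from epp.modal import build_cluster_graph
        graph = build_cluster_graph(labels, grid.density, grid.weights, cfg)
        (pt, _) = edge_saddle(grid.density, graph.edges[0].points)
        assert abs(pt[0] / (GRID - 1) - 0.5) <= 0.05


class TestDipSignificance:
    def test_zero_dip_never_significant(self):
        var = np.full((GRID, GRID), 1e-4)
        sig, stat = dip_significant((0.5, 0.5), ((10, 10), (20, 20)),
                                    0.5, (15, 15), var, 0.05, 1)
        assert not sig and stat == 0.0

    def test_deep_dip_significant(self):
        var = np.full((GRID, GRID), 1e-6)
        sig, stat = dip_significant((1.0, 0.9), ((10, 10), (20, 20)),
                                    0.1, (15, 15), var, 0.05, 1)
        assert sig and stat > 100

    def test_bonferroni_is_stricter(self):
        var = np.full((GRID, GRID), 1e-2)
        args = ((0.5, 0.5), ((10, 10), (20, 20)), 0.25, (15, 15), var, 0.05)
        sig1, _ = dip_significant(*args, 1)
        sig20, _ = dip_significant(*args, 20)
        assert sig1 and not sig20

    def test_variance_grid_predicts_monte_carlo_variance(self):
        """The squared-kernel variance estimate should track the empirical
        replicate-to-replicate variance of the KDE at the centre."""
        rng = np.random.default_rng(42)
        vals, preds = [], []
        for _ in range(150):
            c = rng.normal(0.5, 0.1, size=(2000, 2)).clip(0, 1)
            g = density_grid(c, 0.02)
            vals.append(g.density[128, 128])
            preds.append(variance_grid(g.weights, 0.02, 2000,
                                       g.scale)[128, 128])
        emp = np.var(vals)
        assert np.mean(preds) == pytest.approx(emp, rel=0.5)


def _chain_graph():
    """Hand-built 3-face chain 1 - 2 - 3 with controllable densities."""
    d = np.zeros((GRID, GRID))
    modes = {1: (40, 128), 2: (128, 128), 3: (216, 128)}
    d[modes[1]] = 1.0
    d[modes[2]] = 0.9
    d[modes[3]] = 0.8
    e0 = np.column_stack([np.full(GRID, 84), np.arange(GRID)])
    e1 = np.column_stack([np.full(GRID, 172), np.arange(GRID)])
    faces = {i: Face(id=i, mode=modes[i], mode_density=d[modes[i]],
                     weight=100.0, members=frozenset({i}))
             for i in (1, 2, 3)}
    vertices = {("b", 0, 1): {"on_border": True, "border_terminal": True},
                ("b", 0, 2): {"on_border": True, "border_terminal": True},
                ("b", 1, 1): {"on_border": True, "border_terminal": True},
                ("b", 1, 2): {"on_border": True, "border_terminal": True}}
    edges = [Edge(id=0, faces=(1, 2), points=e0,
                  terminals=(("b", 0, 1), ("b", 0, 2))),
             Edge(id=1, faces=(2, 3), points=e1,
                  terminals=(("b", 1, 1), ("b", 1, 2)))]
    return ClusterGraph(faces=faces, edges=edges, vertices=vertices), d


class TestMergeInsignificant:
    def test_all_significant_graph_unchanged(self):
        graph, d = _chain_graph()
        d[84, :] = 0.05
        d[172, :] = 0.05
        var = np.full((GRID, GRID), 1e-6)
        pruned, results = merge_insignificant(graph, d, var)
        assert len(pruned.faces) == 3 and len(pruned.edges) == 2
        assert all(r.significant for r in results)

    def test_insignificant_middle_dip_merges_to_higher_mode(self):
        graph, d = _chain_graph()
        d[84, :] = 0.85     # shallow dip between faces 1 and 2
        d[172, :] = 0.05    # deep dip between 2 and 3
        var = np.full((GRID, GRID), 1e-2)   # makes only the shallow dip fail
        pruned, _ = merge_insignificant(graph, d, var)
        assert len(pruned.faces) == 2 and len(pruned.edges) == 1
        merged = pruned.faces[1]
        assert merged.members == frozenset({1, 2})
        assert merged.mode_density == 1.0   # higher of the merged modes
        assert merged.weight == 200.0

    def test_two_cluster_full_merge_drops_pair(self):
        graph, d = _chain_graph()
        graph.faces.pop(3)
        graph.edges = graph.edges[:1]
        d[84, :] = 0.95
        var = np.full((GRID, GRID), 1.0)
        pruned, _ = merge_insignificant(graph, d, var)
        assert len(pruned.faces) == 1 and len(pruned.edges) == 0

    def test_pruning_is_idempotent(self):
        graph, d = _chain_graph()
        d[84, :] = 0.85
        d[172, :] = 0.05
        var = np.full((GRID, GRID), 1e-2)
        pruned, _ = merge_insignificant(graph, d, var)
        again, _ = merge_insignificant(pruned, d, var)
        assert len(again.faces) == len(pruned.faces)
        assert [e.id for e in again.edges] == [e.id for e in pruned.edges]

    def test_saddle_invariant_below_modes(self, two_gauss_partition):
        grid, labels, cfg = two_gauss_partition
        from epp.modal import build_cluster_graph
        graph = build_cluster_graph(labels, grid.density, grid.weights, cfg)
        var = variance_grid(grid.weights, grid.kernel_sd, grid.n_events,
                            grid.scale)
        pruned, results = merge_insignificant(graph, grid.density, var)
        for r in results:
            assert r.saddle_density <= min(r.mode_densities) + 1e-9


class TestPowerAndTypeI:
    def test_separated_modes_detected(self):
        rng = np.random.default_rng(0)
        cfg = RunConfig()
        hits = 0
        for s in range(10):
            r = np.random.default_rng(100 + s)
            c = np.clip(np.vstack([r.normal((0.3, 0.5), 0.03, (25000, 2)),
                                   r.normal((0.7, 0.5), 0.03, (25000, 2))]),
                        0, 1)
            hits += len(analyze_pair(c, (0, 1), cfg)) > 0
        assert hits == 10

    def test_single_gaussian_rarely_splits(self):
        cfg = RunConfig()
        splits = 0
        for s in range(10):
            r = np.random.default_rng(200 + s)
            c = np.clip(r.normal(0.5, 0.05, size=(20000, 2)), 0, 1)
            splits += len(analyze_pair(c, (0, 1), cfg)) > 0
        assert splits <= 1
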