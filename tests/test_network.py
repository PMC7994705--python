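"""Full network, spanning tree, and sparsity thresholding."""

import numpy as np
import pytest

from hanet.network import (
    BrainGraph,
    full_network,
    maximum_spanning_tree,
    n_edges_at_sparsity,
    sparsity_sweep,
    threshold_by_sparsity,
)
from hanet.voxel_nodes import RoiSignalMatrix

from oracles import all_spanning_trees_max_weight, pearson_direct, random_correlation_graph


def signal_matrix(arr):
    arr = np.asarray(arr, float)
    return RoiSignalMatrix(arr, roi_labels=np.arange(1, len(arr) + 1), method="test")


class TestFullNetwork:
    def test_identical_rows_weight_one(self):
        sig = signal_matrix([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 3.0, 2.0]])
        g = full_network(sig)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_rows_zeroed(self):
        sig = signal_matrix([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        g = full_network(sig)
        assert g.weights[0, 1] == 0.0

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(12)
        arr = rng.standard_normal((4, 25))
        g = full_network(signal_matrix(arr))
        for i in range(4):
            for j in range(4):
                want = 0.0 if i == j else max(pearson_direct(arr[i], arr[j]), 0.0)
                assert g.weights[i, j] == pytest.approx(want, abs=1e-12)

    def test_constant_row_names_region(self):
        sig = signal_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="1"):
            full_network(sig)


class TestMaximumSpanningTree:
    def test_ninety_node_tree_has_89_edges(self):
        w = random_correlation_graph(90, np.random.default_rng(0))
        g = BrainGraph(w, kind="full")
        tree = maximum_spanning_tree(g)
        assert tree.n_nodes == 90
        assert tree.n_edges == 89
        gx = tree.to_networkx()
        import networkx as nx

        assert nx.is_connected(gx)
        assert nx.is_tree(gx)

    def test_two_nodes_single_edge(self):
        w = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = maximum_spanning_tree(BrainGraph(w, kind="full"))
        assert tree.n_edges == 1
        assert tree.weights[0, 1] == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(10))
    def test_total_weight_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        w = random_correlation_graph(n, rng)
        tree = maximum_spanning_tree(BrainGraph(w, kind="full"))
        got = tree.weights.sum() / 2.0
        assert got == pytest.approx(all_spanning_trees_max_weight(w), abs=1e-9)

    def test_disconnected_graph_reports_components(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(ValueError, match="2 components"):
            maximum_spanning_tree(BrainGraph(w, kind="full"))


class TestSparsityThreshold:
    def test_edge_budget_at_12_percent_of_90_nodes(self):
        assert n_edges_at_sparsity(90, 0.12) == 481
        w = random_correlation_graph(90, np.random.default_rng(5))
        g = threshold_by_sparsity(BrainGraph(w, kind="full"), 0.12)
        assert g.n_edges == 481

    def test_full_sparsity_is_identity_on_positive_graph(self):
        w = np.array(
            [[0.0, 0.5, 0.2], [0.5, 0.0, 0.9], [0.2, 0.9, 0.0]]
        )
        g = threshold_by_sparsity(BrainGraph(w, kind="full"), 1.0)
        assert np.allclose(g.weights, w)

    def test_kept_weights_dominate_discarded(self):
        w = random_correlation_graph(30, np.random.default_rng(7))
        g = threshold_by_sparsity(BrainGraph(w, kind="full"), 0.2)
        kept = g.weights[g.weights > 0]
        dropped = w[(w > 0) & (g.weights == 0)]
        assert kept.min() >= dropped.max() - 1e-12

    def test_tie_break_is_deterministic_by_index(self):
        w = np.zeros((4, 4))
        for i, j, v in [(0, 1, 0.9), (0, 2, 0.5), (1, 3, 0.5), (2, 3, 0.1)]:
            w[i, j] = w[j, i] = v
        # budget of 2 edges: 0.9 plus the tie at 0.5 won by lower (i, j)
        g = threshold_by_sparsity(BrainGraph(w, kind="full"), 2 / 6)
        assert g.weights[0, 2] == pytest.approx(0.5)
        assert g.weights[1, 3] == 0.0

    def test_budget_exceeding_positive_edges_warns(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.warns(UserWarning, match="keeping all"):
            g = threshold_by_sparsity(BrainGraph(w, kind="full"), 1.0)
        assert g.n_edges == 1
        assert g.achieved_sparsity == pytest.approx(0.1)

    def test_zero_budget_raises(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.raises(ValueError, match="zero edges"):
            threshold_by_sparsity(BrainGraph(w, kind="full"), 0.01)

    def test_ensure_connected_unions_tree_edges(self):
        w = random_correlation_graph(20, np.random.default_rng(9))
        g = threshold_by_sparsity(BrainGraph(w, kind="full"), 0.06, ensure_connected=True)
        import networkx as nx

        assert nx.is_connected(g.to_networkx())


class TestSparsitySweep:
    def test_default_sweep_has_six_levels(self):
        w = random_correlation_graph(20, np.random.default_rng(2))
        graphs = sparsity_sweep(BrainGraph(w, kind="full"))
        assert len(graphs) == 6
        assert [g.sparsity for g in graphs] == [0.06, 0.12, 0.18, 0.24, 0.30, 0.36]

    @pytest.mark.parametrize("seed", range(10))
    def test_edge_sets_nested_across_sweep(self, seed):
        w = random_correlation_graph(25, np.random.default_rng(seed))
        graphs = sparsity_sweep(BrainGraph(w, kind="full"))
        for a, b in zip(graphs, graphs[1:]):
            ea = set(map(tuple, np.argwhere(a.weights > 0)))
            eb = set(map(tuple, np.argwhere(b.weights > 0)))
            assert ea.issubset(eb)

    def test_singleton_sweep_matches_direct_call(self):
        w = random_correlation_graph(15, np.random.default_rng(3))
        g = BrainGraph(w, kind="full")
        sweep = sparsity_sweep(g, (0.12,))
        direct = threshold_by_sparsity(g, 0.12)
        assert np.allclose(sweep[0].weights, direct.weights)


def test_all_operations_preserve_symmetry_and_zero_diagonal():
    rng = np.random.default_rng(4)
    w = random_correlation_graph(20, rng)
    g = BrainGraph(w, kind="full")
    for out in [maximum_spanning_tree(g), *sparsity_sweep(g)]:
        assert np.allclose(out.weights, out.weights.T)
        assert np.all(np.diag(out.weights) == 0)
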