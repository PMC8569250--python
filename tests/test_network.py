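import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocoh.network import (
    DEFAULT_THRESHOLDS,
    efficiency_auc,
    efficiency_curve,
    global_efficiency,
    shortest_paths,
    threshold_graph,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_shortest_paths(adj):
    """Exhaustive simple-path enumeration; adj entries are weights (0 = no edge)."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = list(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            for r in range(n - 1):
                for mid in itertools.permutations([k for k in nodes if k not in (i, j)], r):
                    path = (i, *mid, j)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if adj[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / adj[a, b]
                    if ok:
                        best = min(best, length)
            D[i, j] = best
    return D


def floyd_warshall(lengths):
    D = lengths.copy()
    n = D.shape[0]
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return D


def _random_symmetric(rng, n, density=1.0):
    w = rng.uniform(0.1, 2.0, (n, n))
    w = (w + w.T) / 2
    mask = rng.uniform(size=(n, n)) < density
    mask = mask | mask.T
    w = np.where(mask, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return w


class TestThresholdGraph:
    def test_full_sparsity_keeps_complete_graph(self, rng):
        w = _random_symmetric(rng, 5)
        g = threshold_graph(w, 1.0)
        assert g.mask.sum() == 5 * 4  # both triangle halves

    def test_keeps_exactly_the_largest_edges(self, rng):
        w = _random_symmetric(rng, 4)
        g = threshold_graph(w, 0.5)
        iu, ju = np.triu_indices(4, k=1)
        weights = sorted(w[iu, ju], reverse=True)
        kept = sorted(g.adjacency()[iu, ju][g.mask[iu, ju]], reverse=True)
        assert len(kept) == 3
        np.testing.assert_allclose(kept, weights[:3])

    def test_tie_break_is_deterministic(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 0.5
        w[0, 2] = w[2, 0] = 0.5  # tie with (2,3)
        masks = {threshold_graph(w, 2 / 6).mask.tobytes() for _ in range(10)}
        assert len(masks) == 1
        g = threshold_graph(w, 2 / 6)
        assert g.mask[0, 1] and g.mask[0, 2] and not g.mask[2, 3]

    def test_retained_edges_keep_original_weights(self, rng):
        w = _random_symmetric(rng, 6)
        g = threshold_graph(w, 0.3)
        adj = g.adjacency()
        assert np.all(adj[g.mask] == w[g.mask])

    def test_asymmetric_input_rejected(self):
        w = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError, match="symmetric"):
            threshold_graph(w, 0.5)

    def test_absolute_mode(self):
        w = np.array([[0, 0.3, 0.6], [0.3, 0, 0.1], [0.6, 0.1, 0]])
        g = threshold_graph(w, 0.3, mode="absolute")
        assert g.mask[0, 1] and g.mask[0, 2] and not g.mask[1, 2]


class TestShortestPaths:
    def test_three_node_path_hand_computed(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        D = shortest_paths(threshold_graph(w, 1.0))
        assert D[0, 2] == pytest.approx(2.0)
        assert D[0, 1] == pytest.approx(1.0)

    def test_complete_unit_graph(self):
        w = np.ones((5, 5)) - np.eye(5)
        D = shortest_paths(threshold_graph(w, 1.0))
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(D[off], 1.0)

    def test_unreachable_pairs_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        D = shortest_paths(threshold_graph(w, 1.0))
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 3])

    def test_matches_floyd_warshall_on_random_8_node_graphs(self, rng):
        for _ in range(100):
            w = _random_symmetric(rng, 8, density=rng.uniform(0.3, 1.0))
            g = threshold_graph(w, 1.0)
            D = shortest_paths(g)
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
            np.fill_diagonal(lengths, 0.0)
            np.testing.assert_allclose(D, floyd_warshall(lengths), rtol=1e-12)

    def test_matches_networkx(self, rng):
        w = _random_symmetric(rng, 7, density=0.6)
        D = shortest_paths(threshold_graph(w, 1.0))
        G = nx.Graph()
        G.add_nodes_from(range(7))
        for i in range(7):
            for j in range(i + 1, 7):
                if w[i, j] > 0:
                    G.add_edge(i, j, weight=1.0 / w[i, j])
        ref = dict(nx.all_pairs_dijkstra_path_length(G))
        for i in range(7):
            for j in range(7):
                expected = ref[i].get(j, np.inf)
                assert D[i, j] == pytest.approx(expected, rel=1e-12)


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        w = np.ones((6, 6)) - np.eye(6)
        D = shortest_paths(threshold_graph(w, 1.0))
        assert global_efficiency(D) == pytest.approx(1.0)

    def test_three_node_unit_path_five_sixths(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        D = shortest_paths(threshold_graph(w, 1.0))
        assert global_efficiency(D) == pytest.approx(5 / 6)

    def test_empty_graph_is_zero(self):
        D = np.full((4, 4), np.inf)
        np.fill_diagonal(D, 0.0)
        assert global_efficiency(D) == 0.0

    def test_fewer_than_two_nodes_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1)))

    def test_exhaustive_oracle_small_graphs(self, rng):
        # random weighted graphs up to 6 nodes vs simple-path enumeration
        for n in (3, 4, 5, 6):
            for _ in range(8):
                w = _random_symmetric(rng, n, density=rng.uniform(0.3, 1.0))
                D = shortest_paths(threshold_graph(w, 1.0))
                D_ref = brute_force_shortest_paths(np.where(w > 0, w, 0.0))
                np.testing.assert_allclose(D, D_ref, rtol=1e-12)
                assert global_efficiency(D) == pytest.approx(
                    global_efficiency(D_ref), rel=1e-12
                )

    def test_all_unweighted_topologies_n4(self):
        # every 4-node unweighted topology, exhaustively
        iu, ju = np.triu_indices(4, k=1)
        for bits in range(2**6):
            w = np.zeros((4, 4))
            for e in range(6):
                if bits >> e & 1:
                    w[iu[e], ju[e]] = w[ju[e], iu[e]] = 1.0
            if not w.any():
                continue
            D = shortest_paths(threshold_graph(w, 1.0))
            D_ref = brute_force_shortest_paths(w)
            assert global_efficiency(D) == pytest.approx(
                global_efficiency(D_ref), rel=1e-12
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 3.0))
    def test_weight_scaling_scales_efficiency(self, seed, c):
        rng = np.random.default_rng(seed)
        w = _random_symmetric(rng, 6, density=0.7)
        if not w.any():
            return
        e1 = global_efficiency(shortest_paths(threshold_graph(w, 1.0)))
        e2 = global_efficiency(shortest_paths(threshold_graph(c * w, 1.0)))
        assert e2 == pytest.approx(c * e1, rel=1e-9)


class TestEfficiencyAucAndCurve:
    def test_constant_curve_auc(self):
        assert efficiency_auc(DEFAULT_THRESHOLDS, [2.5] * 7) == pytest.approx(2.5 * 0.3)

    def test_linear_curve_exact(self):
        t = np.asarray(DEFAULT_THRESHOLDS)
        v = 3.0 * t + 1.0
        exact = 3.0 * (0.4**2 - 0.1**2) / 2 + 1.0 * 0.3
        assert efficiency_auc(t, v) == pytest.approx(exact, rel=1e-12)

    def test_auc_invariant_to_grid_order(self, rng):
        t = np.asarray(DEFAULT_THRESHOLDS)
        v = rng.uniform(size=7)
        perm = rng.permutation(7)
        assert efficiency_auc(t[perm], v[perm]) == pytest.approx(efficiency_auc(t, v))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            efficiency_auc([0.1], [1.0])

    def test_efficiency_nondecreasing_in_sparsity(self, rng):
        for _ in range(10):
            w = _random_symmetric(rng, 10)
            metrics = efficiency_curve(w)
            assert np.all(np.diff(metrics.eglobal) >= -1e-12)
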