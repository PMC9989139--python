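"""Flexibility, clustering and efficiency metrics against brute-force oracles."""

import numpy as np
import pytest

from threatnet.connectivity import DensityGrid
from threatnet.graphmetrics import (
    clustering_coefficient,
    global_efficiency,
    is_fragmented,
    local_efficiency,
    metrics_over_densities,
    node_flexibility,
)


def random_graph(rng, n, p=0.3):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


def bfs_distances(A):
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(A[u]):
                    if D[s, v] == np.inf:
                        D[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return D


class TestFlexibility:
    def test_constant_labels_rigid(self):
        f, F = node_flexibility(np.ones((3, 5)))
        assert np.allclose(f, 0) and F == 0

    def test_alternating_labels_maximally_flexible(self):
        f, _ = node_flexibility(np.array([[1, 2, 1, 2, 1]]))
        assert f[0] == 1.0

    def test_matches_transition_count_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 20))
            T = int(rng.integers(2, 10))
            Q = rng.integers(0, 4, size=(n, T))
            f, F = node_flexibility(Q)
            expected = np.array(
                [sum(Q[i, t] != Q[i, t + 1] for t in range(T - 1)) / (T - 1)
                 for i in range(n)]
            )
            assert np.array_equal(f, expected)
            assert F == pytest.approx(expected.mean())

    def test_invariant_to_global_relabelling(self, rng):
        Q = rng.integers(0, 5, size=(10, 6))
        perm = rng.permutation(5)
        f1, _ = node_flexibility(Q)
        f2, _ = node_flexibility(perm[Q])
        assert np.array_equal(f1, f2)

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError, match="T >= 2"):
            node_flexibility(np.ones((3, 1)))


class TestClustering:
    def test_triangle_fully_clustered(self):
        A = np.ones((3, 3)) - np.eye(3)
        C, mean = clustering_coefficient(A)
        assert np.allclose(C, 1.0) and mean == 1.0

    def test_path_centre_unclustered(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        C, _ = clustering_coefficient(A)
        assert C[1] == 0.0

    def test_matches_triangle_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 20))
            A = random_graph(rng, n)
            C, _ = clustering_coefficient(A)
            for i in range(n):
                nbrs = np.flatnonzero(A[i])
                k = len(nbrs)
                if k < 2:
                    assert C[i] == 0.0
                    continue
                tri = sum(
                    A[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1:]
                )
                assert C[i] == pytest.approx(tri / (k * (k - 1) / 2), abs=1e-12)


class TestEfficiency:
    def test_complete_graph_unit_efficiency(self):
        A = np.ones((4, 4)) - np.eye(4)
        assert global_efficiency(A) == pytest.approx(1.0)

    def test_path_three_nodes(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        assert global_efficiency(A) == pytest.approx(5 / 6)

    def test_matches_bfs_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 25))
            A = random_graph(rng, n)
            D = bfs_distances(A)
            inv = 1.0 / D
            inv[~np.isfinite(inv)] = 0
            np.fill_diagonal(inv, 0)
            assert global_efficiency(A) == pytest.approx(
                inv.sum() / (n * (n - 1)), abs=1e-12
            )

    def test_local_efficiency_complete_graph(self):
        A = np.ones((4, 4)) - np.eye(4)
        eff, mean = local_efficiency(A)
        assert np.allclose(eff, 1.0) and mean == 1.0

    def test_star_centre_zero(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1
        eff, _ = local_efficiency(A)
        assert eff[0] == 0.0

    def test_correlates_with_clustering_on_random_graphs(self, rng):
        # local efficiency approximates clustering on undirected graphs
        rs = []
        for _ in range(20):
            A = random_graph(rng, 60, p=0.3)
            C, _ = clustering_coefficient(A)
            E, _ = local_efficiency(A)
            rs.append(np.corrcoef(C, E)[0, 1])
        assert np.mean(rs) >= 0.6

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError, match="2 nodes"):
            global_efficiency(np.zeros((1, 1)))


class TestMetricsOverDensities:
    def test_complete_weight_matrix_saturates_at_full_density(self):
        # proportional thresholding keeps only ceil(d*M) edges, so a
        # complete-weight matrix saturates the metrics exactly at density 1
        table = metrics_over_densities(
            np.ones((8, 8)) - np.eye(8), DensityGrid(0.5, 1.0, 2)
        )
        full = table[np.isclose(table["density"], 1.0)]
        for metric in ("clustering", "global_efficiency", "local_efficiency"):
            vals = full[full["metric"] == metric]["value"]
            assert np.allclose(vals, 1.0)

    def test_twenty_density_rows_per_metric(self, rng):
        W = rng.random((10, 10))
        W = np.triu(W, 1) + np.triu(W, 1).T
        table = metrics_over_densities(W, DensityGrid())
        counts = table.groupby("metric")["density"].count()
        assert (counts == 20).all()

    def test_global_efficiency_monotone_in_density(self, rng):
        W = rng.random((15, 15))
        W = np.triu(W, 1) + np.triu(W, 1).T
        table = metrics_over_densities(W, DensityGrid())
        ge = table[table["metric"] == "global_efficiency"].sort_values("density")
        assert (np.diff(ge["value"].to_numpy()) >= -1e-12).all()

    def test_fragmentation_flagged_not_dropped(self):
        W = np.zeros((10, 10))
        W[0, 1] = W[1, 0] = 1.0  # single edge: heavily fragmented
        table = metrics_over_densities(W, DensityGrid(0.1, 0.2, 3))
        assert table["fragmented"].any()
        assert len(table) == 3 * 3

    def test_fragmentation_predicate(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1
        assert is_fragmented(A)
        K = np.ones((4, 4)) - np.eye(4)
        assert not is_fragmented(K)
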