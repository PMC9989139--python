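"""Louvain consensus community detection and dynamic assignments."""

import numpy as np
import pandas as pd
import pytest

from conftest import adjusted_rand, planted_block_graph
from threatnet.communities import (
    consensus_partition,
    default_gamma_grid,
    dynamic_assignment,
    louvain_partition,
    match_labels,
    modularity,
    multilayer_modularity,
    select_gamma,
    sweep_parameters,
)


class TestModularity:
    def test_two_triangles_half(self, two_triangles):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity(two_triangles, labels, 1.0) == pytest.approx(0.5)

    def test_single_community_zero(self, rng):
        A, _ = planted_block_graph(rng, n=30, k=3)
        assert modularity(A, np.zeros(30), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            A = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            A = np.triu(A, 1) + np.triu(A, 1).T
            if A.sum() == 0:
                continue
            labels = rng.integers(0, 3, size=n)
            gamma = float(rng.uniform(0.5, 2.0))
            two_m = A.sum()
            k = A.sum(axis=1)
            q = 0.0
            for i in range(n):
                for j in range(n):
                    if labels[i] == labels[j]:
                        q += A[i, j] - gamma * k[i] * k[j] / two_m
            assert modularity(A, labels, gamma) == pytest.approx(
                q / two_m, abs=1e-12
            )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="m = 0"):
            modularity(np.zeros((4, 4)), np.zeros(4))


class TestLouvain:
    def test_recovers_two_triangles(self, two_triangles):
        labels = louvain_partition(two_triangles, seed=0)
        assert len(np.unique(labels)) == 2
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]

    def test_complete_graph_single_community(self):
        A = np.ones((6, 6)) - np.eye(6)
        assert len(np.unique(louvain_partition(A, seed=1))) == 1

    def test_planted_blocks_recovered(self, rng):
        A, truth = planted_block_graph(rng)
        labels = louvain_partition(A, seed=2)
        assert adjusted_rand(truth, labels) >= 0.9

    def test_asymmetric_input_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            louvain_partition(A)


class TestConsensus:
    def test_unambiguous_optimum_fully_stable(self, two_triangles):
        labels, stability, P = consensus_partition(two_triangles, n_iter=50, seed=0)
        assert np.allclose(stability, 1.0)
        expected = np.zeros((6, 6))
        expected[:3, :3] = 1
        expected[3:, 3:] = 1
        assert np.array_equal(P, expected)

    def test_planted_blocks_high_stability(self, rng):
        A, truth = planted_block_graph(rng)
        labels, stability, _ = consensus_partition(A, n_iter=100, seed=3)
        assert adjusted_rand(truth, labels) >= 0.9
        assert stability.mean() >= 0.8

    def test_permutation_invariance(self, rng, two_triangles):
        perm = rng.permutation(6)
        A_p = two_triangles[np.ix_(perm, perm)]
        lab, _, _ = consensus_partition(two_triangles, n_iter=20, seed=4)
        lab_p, _, _ = consensus_partition(A_p, n_iter=20, seed=4)
        # permuted input yields the permuted partition (up to label names)
        assert adjusted_rand(lab[perm], lab_p) == pytest.approx(1.0)

    def test_matching_partition_to_itself_is_identity(self, rng):
        labels = rng.integers(1, 5, size=20)
        assert np.array_equal(match_labels(labels, labels), labels)


class TestSweep:
    def test_default_grid_has_31_values(self):
        assert len(default_gamma_grid()) == 31

    def test_single_gamma_single_row(self, two_triangles):
        table = sweep_parameters(two_triangles, [1.0], n_iter=10)
        assert len(table) == 1

    def test_community_count_grows_with_resolution(self, two_triangles):
        table = sweep_parameters(two_triangles, [0.5, 5.0], n_iter=20)
        n_lo, n_hi = table["n_communities"]
        assert n_lo <= n_hi
        assert n_lo == 2

    def test_select_gamma_targets_community_count(self):
        sweep = pd.DataFrame(
            {"gamma": [1.0, 1.5, 2.0], "n_communities": [3, 6, 9],
             "mean_stability": [0.9, 0.8, 0.7]}
        )
        assert select_gamma(sweep, target_n=6) == 1.5


class TestDynamicAssignment:
    def test_identical_layers_zero_flexibility(self, rng):
        A, _ = planted_block_graph(rng, n=30, k=3)
        dyn = dynamic_assignment([A, A, A], omega=0.0, n_iter=10, seed=0)
        assert (dyn.Q == dyn.Q[:, :1]).all()

    def test_planted_switch_recovered(self, rng):
        # 10 nodes spread over blocks change membership at layer 4
        lab1 = np.repeat(np.arange(6), 10)
        switchers = np.arange(0, 60, 6)
        lab2 = lab1.copy()
        lab2[switchers] = (lab1[switchers] + 1) % 6
        layers = [planted_block_graph(rng, labels=lab1)[0] for _ in range(3)]
        layers += [planted_block_graph(rng, labels=lab2)[0] for _ in range(3)]
        dyn = dynamic_assignment(layers, omega=0.5, n_iter=20, seed=5)
        switched = dyn.Q[:, 3] != dyn.Q[:, 2]
        assert switched[switchers].sum() >= 9
        assert switched[np.setdiff1d(np.arange(60), switchers)].sum() <= 5

    def test_stronger_coupling_never_raises_flexibility(self, rng):
        lab = np.repeat(np.arange(3), 8)
        layers = [planted_block_graph(rng, labels=lab, p_in=0.4, p_out=0.2)[0]
                  for _ in range(4)]
        flex = []
        for omega in (0.0, 0.5, 5.0):
            dyn = dynamic_assignment(layers, omega=omega, n_iter=10, seed=6)
            flex.append((dyn.Q[:, 1:] != dyn.Q[:, :-1]).mean())
        assert flex[0] >= flex[1] >= flex[2]

    def test_multilayer_quality_prefers_planted_assignment(self, rng):
        lab = np.repeat(np.arange(3), 8)
        layers = [planted_block_graph(rng, labels=lab)[0] for _ in range(3)]
        Q_true = np.tile(lab[:, None], (1, 3))
        Q_rand = rng.integers(0, 3, size=Q_true.shape)
        q_true = multilayer_modularity(layers, Q_true, 1.0, 0.5)
        q_rand = multilayer_modularity(layers, Q_rand, 1.0, 0.5)
        assert q_true > q_rand

    def test_mismatched_node_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="node set"):
            dynamic_assignment([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_needs_two_layers(self):
        with pytest.raises(ValueError, match="2 layers"):
            dynamic_assignment([np.zeros((4, 4))])
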