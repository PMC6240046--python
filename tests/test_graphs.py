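"""Connectivity matrices, FDR thresholding, Louvain modules and
participation coefficients, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmrconn import graphs as gr
from tmrconn.betaseries import BetaSeries


def brute_force_pc(W, labels):
    """Per-node participation coefficient by explicit per-module summation."""
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = W[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for s in set(labels):
            kappa = sum(W[i, j] for j in range(n) if labels[j] == s)
            acc += (kappa / k) ** 2
        out[i] = 1.0 - acc
    return out


def random_modular_graph(rng, n=None):
    n = n or rng.integers(5, 30)
    W = np.abs(rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    W[rng.random((n, n)) < 0.5] = 0
    W = np.triu(W, 1)
    W = W + W.T
    labels = rng.integers(1, 4, size=n)
    return W, labels


class TestCorrelation:
    def test_toy_matches_direct_pearson_formula(self, rng):
        data = rng.standard_normal((3, 5))
        g = gr.correlation_matrix(BetaSeries(data, np.repeat("cue", 5)))
        for i in range(3):
            for j in range(i + 1, 3):
                x, y = data[i] - data[i].mean(), data[j] - data[j].mean()
                r = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert g.weights[i, j] == pytest.approx(r, abs=1e-12)
        assert np.all(np.diag(g.weights) == 0)

    def test_identical_and_negated_series(self):
        x = np.array([1.0, 2.0, 0.5, 3.0])
        data = np.vstack([x, x, -x])
        g = gr.correlation_matrix(BetaSeries(data, np.repeat("cue", 4)))
        assert g.weights[0, 1] == pytest.approx(1.0)
        assert g.weights[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_node_listed(self):
        data = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match=r"\[0\]"):
            gr.correlation_matrix(BetaSeries(data, np.repeat("cue", 5)))

    def test_too_few_trials(self):
        with pytest.raises(ValueError, match="3 trials"):
            gr.correlation_matrix(BetaSeries(np.ones((2, 2)), np.repeat("cue", 2)))


class TestThreshold:
    def test_step_up_enumeration_example(self):
        # p = {0.001, 0.02, 0.04, 0.8}, m=4, q=0.05: thresholds i*q/m are
        # {0.0125, 0.025, 0.0375, 0.05} so exactly the first two survive
        reject = gr.bh_reject(np.array([0.001, 0.02, 0.04, 0.8]), 0.05)
        assert list(reject) == [True, True, False, False]

    def test_strong_positive_edges_all_survive(self):
        W = np.full((4, 4), 0.999)
        np.fill_diagonal(W, 0)
        g = gr.ConnectivityGraph(W, n_trials=50)
        out = gr.threshold_fdr(g)
        assert out.threshold["n_edges_kept"] == 6
        assert np.all(out.weights[np.triu_indices(4, 1)] > 0)

    def test_all_negative_gives_empty_flagged_graph(self):
        W = np.full((4, 4), -0.9)
        np.fill_diagonal(W, 0)
        g = gr.ConnectivityGraph(W, n_trials=50)
        with pytest.warns(UserWarning, match="no edges"):
            out = gr.threshold_fdr(g)
        assert out.threshold["n_edges_kept"] == 0
        assert np.all(out.weights == 0)

    def test_monotone_in_q(self, rng):
        W = np.clip((rng.random((30, 30)) - 0.4), -1, 1)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        g = gr.ConnectivityGraph(W, n_trials=40)
        strict = gr.threshold_fdr(g, q=0.01).weights != 0
        loose = gr.threshold_fdr(g, q=0.05).weights != 0
        assert np.all(loose[strict])

    def test_needs_enough_trials(self):
        g = gr.ConnectivityGraph(np.zeros((3, 3)), n_trials=3)
        with pytest.raises(ValueError):
            gr.threshold_fdr(g)


class TestParcelAverage:
    def test_identity_when_one_voxel_per_parcel(self, rng):
        data = rng.standard_normal((4, 6))
        betas = BetaSeries(data, np.repeat("cue", 6))
        out = gr.parcel_average(betas, np.array([1, 2, 3, 4]))
        assert np.allclose(out.data, data)

    def test_two_voxel_parcel_is_mean(self, rng):
        a, b = rng.standard_normal((2, 5))
        betas = BetaSeries(np.vstack([a, b]), np.repeat("cue", 5))
        out = gr.parcel_average(betas, np.array([1, 1]))
        assert np.allclose(out.data[0], (a + b) / 2)

    def test_region_matrix_is_115_square(self, parcellation10, rng):
        n_vox = parcellation10.size
        betas = BetaSeries(rng.standard_normal((n_vox, 10)), np.repeat("cue", 10))
        parcels = gr.parcel_average(betas, parcellation10)
        g = gr.correlation_matrix(parcels)
        assert g.weights.shape == (115, 115)

    def test_empty_parcel_rejected(self, rng):
        betas = BetaSeries(rng.standard_normal((3, 5)), np.repeat("cue", 5))
        with pytest.raises(ValueError, match="empty"):
            gr.parcel_average(betas, np.array([1, 1, 3]))


class TestLouvain:
    def test_two_triangles_give_two_modules_q_half(self):
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            W[a, b] = W[b, a] = 1.0
        part = gr.louvain_partition(
            gr.ConnectivityGraph(W, n_trials=10), n_restarts=10, rng_seed=0
        )
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5, abs=1e-12)
        # Q matches a direct evaluation of the modularity formula
        assert part.q == pytest.approx(gr.modularity_q(W, part.labels), abs=1e-10)

    def test_single_clique_single_module_q_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        part = gr.louvain_partition(
            gr.ConnectivityGraph(W, n_trials=10), n_restarts=5, rng_seed=0
        )
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_rejected(self):
        g = gr.ConnectivityGraph(np.zeros((4, 4)), n_trials=10)
        with pytest.raises(ValueError, match="edge"):
            gr.louvain_partition(g)

    def test_q_never_below_single_module_baseline(self, rng):
        for _ in range(10):
            W, _ = random_modular_graph(rng)
            if not np.any(W > 0):
                continue
            part = gr.louvain_partition(
                gr.ConnectivityGraph(W, n_trials=10), n_restarts=5, rng_seed=1
            )
            assert part.q >= 0.0 - 1e-12  # Q(all-one-module) = 0


class TestPropagate:
    def test_voxels_inherit_parcel_modules(self):
        part = gr.ModulePartition(labels=np.array([1, 2]), q=0.0)
        parc = np.array([1, 1, 1, 2, 2])
        assert list(gr.propagate_modules(part, parc)) == [1, 1, 1, 2, 2]

    def test_single_module_everywhere(self):
        part = gr.ModulePartition(labels=np.array([1, 1, 1]), q=0.0)
        parc = np.array([3, 1, 2, 2])
        assert list(gr.propagate_modules(part, parc)) == [1, 1, 1, 1]

    def test_relabelling_invariance(self, rng):
        parc = rng.integers(1, 5, size=20)
        labels = np.array([1, 2, 2, 1])
        part = gr.ModulePartition(labels=labels, q=0.0)
        vox = gr.propagate_modules(part, parc)
        # permute parcel ids together with the partition rows
        perm = np.array([2, 0, 3, 1])  # new parcel id = position of old
        inv = np.argsort(perm)
        parc_perm = inv[parc - 1] + 1
        part_perm = gr.ModulePartition(labels=labels[perm], q=0.0)
        assert np.array_equal(gr.propagate_modules(part_perm, parc_perm), vox)

    def test_uncovered_parcel_rejected(self):
        part = gr.ModulePartition(labels=np.array([1]), q=0.0)
        with pytest.raises(ValueError, match="cover"):
            gr.propagate_modules(part, np.array([1, 2]))


class TestParticipation:
    def test_provincial_node_scores_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = 2.0
        labels = np.array([1, 1, 1, 2])
        g = gr.ConnectivityGraph(W, n_trials=10)
        assert gr.participation_coefficient(g, labels)[0] == 0.0

    def test_even_split_two_modules_gives_half(self):
        # 2 unit edges in-module, 2 into one other module: 1 - 2*(0.5^2)
        W = np.zeros((5, 5))
        for j in (1, 2, 3, 4):
            W[0, j] = W[j, 0] = 1.0
        labels = np.array([1, 1, 1, 2, 2])
        g = gr.ConnectivityGraph(W, n_trials=10)
        assert gr.participation_coefficient(g, labels)[0] == pytest.approx(0.5)

    def test_weighted_three_to_one_split(self):
        # strength 3 in-module, 1 to another module: 1 - (0.75^2 + 0.25^2)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 3.0
        W[0, 2] = W[2, 0] = 1.0
        labels = np.array([1, 1, 2])
        g = gr.ConnectivityGraph(W, n_trials=10)
        assert gr.participation_coefficient(g, labels)[0] == pytest.approx(0.375)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            W, labels = random_modular_graph(rng)
            g = gr.ConnectivityGraph(W, n_trials=10)
            assert np.allclose(
                gr.participation_coefficient(g, labels),
                brute_force_pc(W, labels),
                atol=1e-12,
            )

    def test_upper_bound_one_minus_inverse_modules(self, rng):
        W, labels = random_modular_graph(rng, n=20)
        g = gr.ConnectivityGraph(W, n_trials=10)
        pc = gr.participation_coefficient(g, labels)
        M = len(np.unique(labels))
        assert np.all(pc <= 1 - 1 / M + 1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        W, labels = random_modular_graph(rng, n=12)
        g1 = gr.ConnectivityGraph(W, n_trials=10)
        g2 = gr.ConnectivityGraph(W * scale, n_trials=10)
        assert np.allclose(
            gr.participation_coefficient(g1, labels),
            gr.participation_coefficient(g2, labels),
            atol=1e-10,
        )

    def test_moving_edge_to_new_module_increases_pc(self, rng):
        for trial in range(20):
            n = 8
            labels = np.array([1] * 4 + [2] * 3 + [3])
            W = np.zeros((n, n))
            # node 0: edges inside module 1 and none to module 3
            W[0, 1] = W[1, 0] = 1.0
            W[0, 2] = W[2, 0] = 1.0
            W[0, 4] = W[4, 0] = rng.random() + 0.1
            before = gr.participation_coefficient(
                gr.ConnectivityGraph(W, n_trials=10), labels
            )[0]
            W2 = W.copy()
            W2[0, 2] = W2[2, 0] = 0.0
            W2[0, 7] = W2[7, 0] = 1.0  # moved to previously unconnected module 3
            after = gr.participation_coefficient(
                gr.ConnectivityGraph(W2, n_trials=10), labels
            )[0]
            assert after > before
            assert after == pytest.approx(brute_force_pc(W2, labels)[0], abs=1e-12)

    def test_zero_strength_node_gets_zero(self):
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 1.0
        g = gr.ConnectivityGraph(W, n_trials=10)
        pc = gr.participation_coefficient(g, np.array([1, 1, 2]))
        assert pc[0] == 0.0
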