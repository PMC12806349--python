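"""Residual GCN: propagation operator, forward pass, training, transfer."""

import numpy as np
import pytest

from chromocnv.gcn import (
    GCNParams,
    TrainConfig,
    evaluate_zero_shot,
    fine_tune,
    gcn_forward,
    normalize_adjacency,
    train_gcn,
)
from chromocnv.graph import build_graph, graph_from_edges
from chromocnv.linear import SplitSpec
from chromocnv.pipeline import run_gcn_pipeline
from chromocnv.synthetic import simulate_chromosome


class TestNormalizeAdjacency:
    def test_edgeless_graph_gives_identity(self):
        g = build_graph(np.zeros((4, 4)))
        assert np.array_equal(normalize_adjacency(g), np.eye(4, dtype=np.float32))

    def test_two_node_single_edge_by_hand(self):
        g = graph_from_edges(2, [(0, 1, 1.0)])
        # W + I = [[1,1],[1,1]], degrees (2,2) -> every entry 0.5
        assert np.allclose(normalize_adjacency(g), 0.5)

    @pytest.mark.parametrize("k,n", [(2, 8), (4, 9)])
    def test_unit_weight_regular_graph_rows_sum_to_one(self, k, n):
        # circulant k-regular graph: all degrees k+1 after self-loops,
        # so each row holds (k+1) entries of 1/(k+1)
        edges = []
        for i in range(n):
            for step in range(1, k // 2 + 1):
                edges.append((i, (i + step) % n, 1.0))
        g = graph_from_edges(n, sorted({(min(u, v), max(u, v), w) for u, v, w in edges}))
        prop = normalize_adjacency(g)
        assert np.allclose(prop.sum(axis=1), 1.0, atol=1e-6)

    def test_symmetry(self, rng):
        v = rng.uniform(0, 2, size=(10, 10))
        v = (v + v.T) / 2
        prop = normalize_adjacency(build_graph(v))
        assert np.allclose(prop, prop.T, atol=1e-7)


def _naive_forward(params, prop, X):
    """Independent re-implementation of the forward map, step by step."""
    A = np.asarray(prop, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    H1 = np.tanh(A.dot(X).dot(np.asarray(params.W1, dtype=np.float64)))
    H2 = np.tanh(A.dot(H1).dot(np.asarray(params.W2, dtype=np.float64)))
    H3 = np.tanh(A.dot(H2).dot(np.asarray(params.W3, dtype=np.float64)))
    H4 = np.tanh(A.dot(H1 + H3).dot(np.asarray(params.W4, dtype=np.float64)))
    logits = H4.dot(np.asarray(params.W5, dtype=np.float64)) + np.asarray(
        params.b5, dtype=np.float64
    )
    return 1.0 / (1.0 + np.exp(-logits))


class TestForward:
    def test_zero_weights_give_half_everywhere(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 2.0)])
        params = GCNParams(
            W1=np.zeros((4, 2), dtype=np.float32),
            W2=np.zeros((2, 2), dtype=np.float32),
            W3=np.zeros((2, 2), dtype=np.float32),
            W4=np.zeros((2, 2), dtype=np.float32),
            W5=np.zeros((2, 4), dtype=np.float32),
            b5=np.zeros(4, dtype=np.float32),
            hidden_dim=2,
        )
        O = gcn_forward(params, normalize_adjacency(g), np.ones((3, 4)))
        assert np.allclose(O, 0.5)

    def test_matches_independent_naive_oracle(self):
        # two-node, hand-sized instance evaluated to 1e-10
        g = graph_from_edges(2, [(0, 1, 1.0)])
        prop = normalize_adjacency(g)
        rng = np.random.default_rng(7)
        params = GCNParams(
            W1=rng.normal(0, 0.3, (3, 2)).astype(np.float64),
            W2=rng.normal(0, 0.3, (2, 2)).astype(np.float64),
            W3=rng.normal(0, 0.3, (2, 2)).astype(np.float64),
            W4=rng.normal(0, 0.3, (2, 2)).astype(np.float64),
            W5=rng.normal(0, 0.3, (2, 4)).astype(np.float64),
            b5=rng.normal(0, 0.3, 4).astype(np.float64),
            hidden_dim=2,
        )
        X = rng.normal(size=(2, 3))
        O = gcn_forward(params, prop.astype(np.float64), X)
        assert np.max(np.abs(O - _naive_forward(params, prop, X))) < 1e-10

    def test_inference_is_deterministic(self):
        g = graph_from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        prop = normalize_adjacency(g)
        params = GCNParams.init(feature_dim=6, hidden_dim=8, seed=0)
        X = np.random.default_rng(1).normal(size=(4, 6))
        a = gcn_forward(params, prop, X, training=False)
        b = gcn_forward(params, prop, X, training=False)
        assert np.array_equal(a, b)
        assert np.all((a > 0) & (a < 1))

    def test_permutation_equivariance_at_inference(self, rng):
        v = rng.uniform(0, 3, size=(9, 9))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        prop = normalize_adjacency(build_graph(v))
        params = GCNParams.init(feature_dim=5, hidden_dim=8, seed=2)
        X = rng.normal(size=(9, 5)).astype(np.float32)
        perm = rng.permutation(9)
        P = np.eye(9, dtype=np.float32)[perm]
        O = gcn_forward(params, prop, X)
        O_perm = gcn_forward(params, P @ prop @ P.T, P @ X)
        assert np.allclose(O_perm, O[perm], atol=1e-5)

    def test_shape_mismatch_rejected(self):
        g = graph_from_edges(2, [(0, 1, 1.0)])
        params = GCNParams.init(feature_dim=6, hidden_dim=4, seed=0)
        with pytest.raises(ValueError, match="feature dim"):
            gcn_forward(params, normalize_adjacency(g), np.ones((2, 3)))


def _small_chromosome(seed=0, n_bins=150, noise="none"):
    return simulate_chromosome(
        n_bins=n_bins, n_segments=4, min_len=10, max_len=20, noise_model=noise, seed=seed
    )


def _small_pipeline(sim, seed=0, **overrides):
    kwargs = dict(d=16, walk_length=20, num_walks=5, window=5, seed=seed)
    kwargs.update(overrides)
    return run_gcn_pipeline(
        sim.matrix,
        sim.labels,
        train_config=TrainConfig(split=SplitSpec(0.6, seed), epochs=120, seed=seed,
                                 hidden_dim=16),
        **kwargs,
    )


class TestTraining:
    def test_loss_decreases_and_labels_recovered(self):
        sim = _small_chromosome()
        res = _small_pipeline(sim)
        assert res.losses[-1] <= res.losses[0]
        assert res.report.accuracy > 0.5  # well above 4-class chance

    def test_single_class_training_split_rejected(self):
        sim = _small_chromosome()
        graph = build_graph(sim.matrix)
        with pytest.raises(ValueError, match="single class"):
            train_gcn(graph, np.ones((150, 8), dtype=np.float32),
                      np.ones(150, dtype=int), TrainConfig())

    def test_reproducible_under_seed(self):
        sim = _small_chromosome()
        a = _small_pipeline(sim, seed=3)
        b = _small_pipeline(sim, seed=3)
        assert np.array_equal(a.params.W1, b.params.W1)
        assert a.report.accuracy == b.report.accuracy

    @pytest.mark.parametrize("d", [16, 32, 64, 128])
    def test_node_feature_dimension_sweep_completes(self, d):
        sim = _small_chromosome()
        res = _small_pipeline(sim, d=d)
        assert res.embeddings.vectors.shape == (150, d)
        assert 0.0 <= res.report.accuracy <= 1.0
        assert np.isfinite(res.report.f1_macro)

    def test_params_npz_round_trip(self, tmp_path):
        params = GCNParams.init(feature_dim=6, hidden_dim=4, seed=5)
        params.save(tmp_path / "m.npz")
        back = GCNParams.load(tmp_path / "m.npz")
        assert np.array_equal(back.W4, params.W4)
        assert back.hidden_dim == 4


class TestTransfer:
    def test_same_distribution_zero_shot_is_accurate(self):
        sim = _small_chromosome(seed=1)
        res = _small_pipeline(sim, seed=1)
        report = evaluate_zero_shot(res.params, res.graph, res.embeddings, sim.labels)
        assert report.accuracy >= 0.85

    def test_degenerate_supervision_rejected(self):
        sim = _small_chromosome(seed=2)
        res = _small_pipeline(sim, seed=2)
        all_neutral = np.ones(150, dtype=int)
        with pytest.raises(ValueError, match="single class"):
            fine_tune(res.params, res.graph, res.embeddings, all_neutral,
                      label_fraction=0.02, seed=0)

    def test_invalid_fraction_rejected(self):
        params = GCNParams.init(feature_dim=4, hidden_dim=4, seed=0)
        g = graph_from_edges(2, [(0, 1, 1.0)])
        with pytest.raises(ValueError, match="label_fraction"):
            fine_tune(params, g, np.ones((2, 4)), np.array([0, 1]), label_fraction=1.5)


def test_ice_normalized_input_accuracy_close_to_raw(standard_runs):
    """Balancing removes coverage bias but the GCN still recovers CNV:
    accuracy on ICE input stays within 5 points of raw input."""
    _, raw = standard_runs(0, "baseline")
    _, iced = standard_runs(0, "ice")
    assert abs(raw.report.accuracy - iced.report.accuracy) <= 0.05
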