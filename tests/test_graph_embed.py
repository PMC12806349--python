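"""Chromosomal graph construction, biased walks, and skip-gram embeddings."""

import numpy as np
import pytest
from scipy.stats import chisquare

from chromocnv.embedding import (
    node2vec_embed,
    read_embeddings,
    train_skipgram,
    write_embeddings,
)
from chromocnv.graph import (
    build_graph,
    generate_walks,
    graph_from_edges,
    walk_transition_probs,
)


class TestBuildGraph:
    def test_single_pair_graph(self):
        g = build_graph(np.array([[0.0, 5.0], [5.0, 0.0]]), min_weight=0.0)
        assert g.edge_set() == {(0, 1, 5.0)}
        assert g.n_edges == 1

    def test_zero_entries_never_make_edges(self, rng):
        v = rng.integers(0, 3, size=(10, 10)).astype(float)
        v = np.triu(v, 1)
        v = v + v.T
        g = build_graph(v, min_weight=0.0)
        for u, w, weight in g.edge_set():
            assert v[u, w] == weight > 0

    def test_traversal_order_irrelevant_for_symmetric_input(self, rng):
        v = rng.uniform(0, 4, size=(12, 12))
        v = np.triu(v, 1)
        v[v < 1] = 0.0
        v = v + v.T
        assert build_graph(v).edge_set() == build_graph(v.T.copy()).edge_set()

    def test_edge_count_bound_and_weight_provenance(self, rng):
        v = rng.uniform(0, 1, size=(15, 15))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 7.0)  # diagonal must be ignored
        g = build_graph(v, min_weight=0.2)
        assert g.n_edges <= 15 * 14 // 2
        for u, w, weight in g.edge_set():
            assert u != w and weight == v[u, w] > 0.2

    def test_top_k_union_sparsification(self):
        # node 0's strongest partner is 1; node 2's strongest is 1 as well;
        # union rule keeps an edge if either endpoint ranks it top-1
        v = np.array(
            [
                [0.0, 9.0, 1.0],
                [9.0, 0.0, 8.0],
                [1.0, 8.0, 0.0],
            ]
        )
        g = build_graph(v, top_k=1)
        assert {(u, w) for u, w, _ in g.edge_set()} == {(0, 1), (1, 2)}


class TestWalkTransitionProbs:
    def test_unbiased_reduces_to_weight_proportional(self):
        g = graph_from_edges(3, [(0, 1, 2.0), (0, 2, 6.0)])
        nbrs, probs = walk_transition_probs(g, prev=None, cur=0, p=1.0, q=1.0)
        lookup = dict(zip(nbrs.tolist(), probs))
        assert lookup[1] == pytest.approx(0.25)
        assert lookup[2] == pytest.approx(0.75)

    def test_triangle_hand_enumeration(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        # prev=0, cur=1: neighbor 0 is the return node (score 1/p),
        # neighbor 2 is adjacent to prev (score 1); p=q=1 gives 0.5/0.5
        nbrs, probs = walk_transition_probs(g, prev=0, cur=1, p=1.0, q=1.0)
        assert np.allclose(probs, [0.5, 0.5])
        # p=2, q=4: return score 1/2, common-neighbor score 1 -> (1/3, 2/3)
        nbrs, probs = walk_transition_probs(g, prev=0, cur=1, p=2.0, q=4.0)
        lookup = dict(zip(nbrs.tolist(), probs))
        assert lookup[0] == pytest.approx(1 / 3)
        assert lookup[2] == pytest.approx(2 / 3)

    def test_out_bias_on_path_graph(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        # prev=0, cur=1: node 2 is NOT adjacent to 0 -> score 1/q
        nbrs, probs = walk_transition_probs(g, prev=0, cur=1, p=1.0, q=0.5)
        lookup = dict(zip(nbrs.tolist(), probs))
        assert lookup[2] == pytest.approx(2 / 3)

    def test_probabilities_sum_to_one(self, rng):
        v = rng.uniform(0.1, 3, size=(8, 8))
        v = v + v.T
        g = build_graph(v)
        _, probs = walk_transition_probs(g, prev=3, cur=4, p=1.7, q=0.3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isolated_node_rejected(self):
        g = build_graph(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="isolated"):
            walk_transition_probs(g, prev=None, cur=0)


class TestGenerateWalks:
    def test_consecutive_pairs_are_edges(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        corpus = generate_walks(g, walk_length=20, num_walks=4, seed=5)
        edges = {(u, v) for u, v, _ in g.edge_set()}
        edges |= {(v, u) for u, v in edges}
        for walk in corpus.walks:
            for a, b in zip(walk[:-1], walk[1:]):
                assert (int(a), int(b)) in edges

    def test_corpus_size_num_walks_per_non_isolated_node(self):
        v = np.zeros((6, 6))
        v[0, 1] = v[1, 0] = 1.0
        v[2, 3] = v[3, 2] = 1.0  # nodes 4, 5 isolated
        g = build_graph(v)
        corpus = generate_walks(g, walk_length=10, num_walks=10, seed=0)
        assert corpus.walks.shape == (10 * 4, 10)

    def test_walks_never_cross_components(self):
        v = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            v[a, b] = v[b, a] = 1.0
        g = build_graph(v)
        corpus = generate_walks(g, walk_length=30, num_walks=5, seed=2)
        for walk in corpus.walks:
            comps = {0 if n <= 2 else 1 for n in walk}
            assert len(comps) == 1

    def test_deterministic_under_seed(self):
        sim_v = np.random.default_rng(3).uniform(0, 2, size=(15, 15))
        v = (sim_v + sim_v.T) / 2
        g = build_graph(v)
        a = generate_walks(g, walk_length=12, num_walks=3, seed=9).walks
        b = generate_walks(g, walk_length=12, num_walks=3, seed=9).walks
        assert np.array_equal(a, b)

    def test_star_first_step_frequencies_match_weights(self):
        # weighted star: center 0 with spokes of weight 1..4
        edges = [(0, k, float(k)) for k in range(1, 5)]
        g = graph_from_edges(5, edges)
        corpus = generate_walks(g, walk_length=2, num_walks=2500, seed=11)
        starts = corpus.walks[corpus.walks[:, 0] == 0]
        counts = np.bincount(starts[:, 1], minlength=5)[1:]
        expected = np.array([1, 2, 3, 4]) / 10 * counts.sum()
        _, pvalue = chisquare(counts, expected)
        assert pvalue > 0.01


class TestSkipgram:
    def _clique_pair_graph(self):
        v = np.zeros((20, 20))
        for block in (range(0, 10), range(10, 20)):
            for i in block:
                for j in block:
                    if i < j:
                        v[i, j] = v[j, i] = 5.0
        v[9, 10] = v[10, 9] = 0.1  # weak bridge
        return build_graph(v)

    def test_cliques_separate_in_embedding_space(self):
        g = self._clique_pair_graph()
        corpus = generate_walks(g, walk_length=30, num_walks=10, seed=0)
        emb = train_skipgram(corpus, d=16, window=5, seed=0)
        vec = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        cos = vec @ vec.T
        within = np.mean([cos[i, j] for i in range(10) for j in range(10) if i != j])
        between = np.mean([cos[i, j] for i in range(10) for j in range(10, 20)])
        assert within > between

    def test_structurally_identical_nodes_are_close(self):
        # nodes 0 and 1 share the same neighbors with the same weights
        edges = [(0, k, 2.0) for k in range(2, 8)] + [(1, k, 2.0) for k in range(2, 8)]
        edges += [(2, 3, 1.0), (4, 5, 1.0), (6, 7, 1.0)]
        g = graph_from_edges(8, edges)
        corpus = generate_walks(g, walk_length=40, num_walks=20, seed=1)
        emb = train_skipgram(corpus, d=8, window=4, seed=1)
        from scipy.spatial.distance import pdist, squareform

        dists = squareform(pdist(emb.vectors))
        median = np.median(dists[np.triu_indices(8, 1)])
        assert dists[0, 1] < median

    def test_output_shape_is_n_nodes_by_64_default(self):
        g = self._clique_pair_graph()
        corpus = generate_walks(g, walk_length=10, num_walks=2, seed=3)
        emb = train_skipgram(corpus, seed=3)
        assert emb.vectors.shape == (20, 64)

    def test_deterministic_under_seed(self):
        g = self._clique_pair_graph()
        corpus = generate_walks(g, walk_length=10, num_walks=3, seed=4)
        a = train_skipgram(corpus, d=12, seed=4).vectors
        b = train_skipgram(corpus, d=12, seed=4).vectors
        assert np.array_equal(a, b)

    def test_invalid_dimension_rejected(self):
        g = self._clique_pair_graph()
        corpus = generate_walks(g, walk_length=5, num_walks=1, seed=0)
        with pytest.raises(ValueError, match="d must"):
            train_skipgram(corpus, d=0)

    def test_isolated_nodes_get_zero_vectors(self):
        v = np.zeros((5, 5))
        v[0, 1] = v[1, 0] = 1.0
        v[1, 2] = v[2, 1] = 1.0
        emb = node2vec_embed(v, d=8, walk_length=10, num_walks=5, window=3, seed=0)
        assert np.array_equal(emb.vectors[3], np.zeros(8))
        assert np.array_equal(emb.vectors[4], np.zeros(8))
        assert not np.allclose(emb.vectors[1], 0)

    def test_embeddings_tsv_round_trip(self, tmp_path):
        g = self._clique_pair_graph()
        emb = node2vec_embed(g, d=6, walk_length=10, num_walks=2, window=3, seed=0)
        write_embeddings(tmp_path / "emb.tsv", emb)
        back = read_embeddings(tmp_path / "emb.tsv")
        assert np.allclose(back.vectors, emb.vectors, atol=1e-6)
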