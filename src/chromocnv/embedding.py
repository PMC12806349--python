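"""Skip-gram node embeddings trained on random-walk corpora.

Implements skip-gram with negative sampling (SGNS): each walk position is a
center node whose nearby nodes (within a dynamic window) are positive
contexts, contrasted against nodes drawn from the unigram^(3/4) noise
distribution.  The learned input vectors are the per-bin features handed to
the GCN.  Nodes absent from the corpus (isolated bins) keep zero vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .graph import ChromGraph, WalkCorpus, build_graph, generate_walks


@dataclass
class EmbeddingMatrix:
    """Per-node feature vectors from node2vec pretraining."""

    vectors: np.ndarray = field(repr=False)
    d: int = 64
    training_meta: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]


_SIG_BOUND = 6.0
_SIG_TABLE_SIZE = 1024


@njit(cache=True, fastmath=True)
def _sgns_kernel(walks, n_nodes, d, window, epochs, lr, negatives, noise_cdf, sig_table, seed):  # pragma: no cover
    np.random.seed(seed)
    w_in = ((np.random.random((n_nodes, d)).astype(np.float32) - np.float32(0.5)) / d)
    w_out = np.zeros((n_nodes, d), dtype=np.float32)
    n_walks, walk_len = walks.shape
    total_steps = epochs * n_walks
    step = 0
    grad = np.empty(d, dtype=np.float32)
    table_scale = _SIG_TABLE_SIZE / (2.0 * _SIG_BOUND)
    for epoch in range(epochs):
        for wi in range(n_walks):
            alpha = np.float32(lr * (1.0 - step / total_steps))
            if alpha < lr * 1e-4:
                alpha = np.float32(lr * 1e-4)
            step += 1
            for pos in range(walk_len):
                center = walks[wi, pos]
                b = 1 + np.int64(np.random.random() * window)  # dynamic window in [1, window]
                lo = max(0, pos - b)
                hi = min(walk_len, pos + b + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = walks[wi, cpos]
                    center_row = w_in[center]
                    for k in range(d):
                        grad[k] = 0.0
                    for neg in range(negatives + 1):
                        if neg == 0:
                            target = context
                            label = np.float32(1.0)
                        else:
                            r = np.random.random()
                            a, bb = 0, n_nodes - 1
                            while a < bb:
                                mid = (a + bb) // 2
                                if noise_cdf[mid] > r:
                                    bb = mid
                                else:
                                    a = mid + 1
                            target = a
                            if target == context:
                                continue
                            label = np.float32(0.0)
                        target_row = w_out[target]
                        dot = np.float32(0.0)
                        for k in range(d):
                            dot += center_row[k] * target_row[k]
                        if dot > _SIG_BOUND:
                            pred = np.float32(1.0)
                        elif dot < -_SIG_BOUND:
                            pred = np.float32(0.0)
                        else:
                            pred = sig_table[np.int64((dot + _SIG_BOUND) * table_scale)]
                        g = (label - pred) * alpha
                        for k in range(d):
                            grad[k] += g * target_row[k]
                        for k in range(d):
                            target_row[k] += g * center_row[k]
                    for k in range(d):
                        center_row[k] += grad[k]
    return w_in


def train_skipgram(
    corpus: WalkCorpus,
    d: int = 64,
    window: int = 10,
    epochs: int = 3,
    lr: float = 0.025,
    negatives: int = 5,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Train SGNS embeddings on a walk corpus.

    Uses a per-position dynamic window (word2vec convention), 5 negative
    samples from the unigram^0.75 distribution, and a linearly decaying
    learning rate.  Deterministic given the seed (single-threaded kernel).
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if corpus.walks.size == 0:
        raise ValueError("empty corpus")
    counts = np.bincount(corpus.walks.ravel(), minlength=corpus.n_nodes).astype(np.float64)
    noise = counts**0.75
    if noise.sum() == 0:
        raise ValueError("corpus covers no nodes")
    noise_cdf = np.cumsum(noise / noise.sum())
    grid = np.linspace(-_SIG_BOUND, _SIG_BOUND, _SIG_TABLE_SIZE, endpoint=False)
    sig_table = (1.0 / (1.0 + np.exp(-grid))).astype(np.float32)
    w_in = _sgns_kernel(
        corpus.walks.astype(np.int32),
        corpus.n_nodes,
        d,
        window,
        epochs,
        np.float64(lr),
        negatives,
        noise_cdf,
        sig_table,
        seed % (2**32),
    )
    vectors = np.asarray(w_in, dtype=np.float64)
    vectors[counts == 0] = 0.0  # isolated nodes: zero embedding
    return EmbeddingMatrix(
        vectors=vectors,
        d=d,
        training_meta={
            "walk_length": corpus.walk_length,
            "num_walks": corpus.num_walks,
            "window": window,
            "p": corpus.p,
            "q": corpus.q,
            "epochs": epochs,
            "lr": lr,
            "negatives": negatives,
            "seed": seed,
        },
    )


def node2vec_embed(
    matrix_or_graph,
    d: int = 64,
    walk_length: int = 100,
    num_walks: int = 10,
    window: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    epochs: int = 3,
    lr: float = 0.025,
    min_weight: float = 0.0,
    top_k: int | None = None,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Full node2vec pretraining: graph -> biased walks -> SGNS vectors."""
    if isinstance(matrix_or_graph, ChromGraph):
        graph = matrix_or_graph
    else:
        graph = build_graph(matrix_or_graph, min_weight=min_weight, top_k=top_k)
    corpus = generate_walks(
        graph, walk_length=walk_length, num_walks=num_walks, p=p, q=q, seed=seed
    )
    return train_skipgram(corpus, d=d, window=window, epochs=epochs, lr=lr, seed=seed)


def write_embeddings(path, emb: EmbeddingMatrix) -> None:
    """Persist embeddings as TSV: node index followed by d values."""
    with open(path, "w") as fh:
        for i, row in enumerate(emb.vectors):
            fh.write(str(i) + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def read_embeddings(path) -> EmbeddingMatrix:
    data = np.loadtxt(path, ndmin=2)
    order = np.argsort(data[:, 0])
    vectors = data[order, 1:]
    return EmbeddingMatrix(vectors=vectors, d=vectors.shape[1])
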