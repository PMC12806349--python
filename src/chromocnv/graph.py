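"""Chromosomal graphs and biased (node2vec-style) random walks.

A contact matrix becomes a weighted undirected graph: one node per bin,
edge weight = interaction count.  Second-order biased walks over this graph
(return bias ``p``, in-out bias ``q``) produce the node sequences fed to the
skip-gram trainer in :mod:`chromocnv.embedding`.  With ``p = q = 1`` the
walk reduces to weight-proportional sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass
class ChromGraph:
    """Weighted undirected graph over chromosome bins, stored as CSR.

    ``indptr``/``indices``/``weights`` give each node's neighbor list
    (indices sorted ascending per node).  Self-loops are never stored; the
    GCN adds its own self-loop term.
    """

    n_nodes: int
    indptr: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    def neighbors(self, u: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.indptr[u], self.indptr[u + 1]
        return self.indices[lo:hi], self.weights[lo:hi]

    def degree(self, u: int) -> int:
        return int(self.indptr[u + 1] - self.indptr[u])

    @property
    def n_edges(self) -> int:
        return int(len(self.indices) // 2)

    @property
    def isolated_nodes(self) -> np.ndarray:
        return np.flatnonzero(np.diff(self.indptr) == 0)

    def edge_set(self) -> set[tuple[int, int, float]]:
        """Edges as (u, v, weight) with u < v — mainly for tests."""
        out = set()
        for u in range(self.n_nodes):
            nbrs, ws = self.neighbors(u)
            for v, w in zip(nbrs, ws):
                if u < v:
                    out.add((int(u), int(v), float(w)))
        return out


def build_graph(matrix, min_weight: float = 0.0, top_k: int | None = None) -> ChromGraph:
    """Build the chromosomal graph from a contact matrix.

    An edge (i, j), i != j, exists iff ``c_ij > min_weight`` and — when
    ``top_k`` is set — j is among i's top_k strongest partners or vice
    versa (union sparsification).  The diagonal is ignored.
    """
    values = np.asarray(getattr(matrix, "values", matrix), dtype=np.float64)
    n = values.shape[0]
    mask = values > min_weight
    np.fill_diagonal(mask, False)
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        off = values.copy()
        np.fill_diagonal(off, -np.inf)
        kth = min(top_k, n - 1)
        order = np.argsort(off, axis=1)[:, ::-1][:, :kth]
        keep = np.zeros_like(mask)
        rows = np.repeat(np.arange(n), kth)
        keep[rows, order.ravel()] = True
        keep |= keep.T
        mask &= keep
    mask = mask | mask.T  # symmetric by construction for symmetric input
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(mask.sum(axis=1))
    indices = np.nonzero(mask)[1].astype(np.int64)
    weights = values[mask]
    return ChromGraph(n_nodes=n, indptr=indptr, indices=indices, weights=weights)


def graph_from_edges(n_nodes: int, edges: list[tuple[int, int, float]]) -> ChromGraph:
    """Construct a ChromGraph from an explicit undirected edge list."""
    values = np.zeros((n_nodes, n_nodes))
    for u, v, w in edges:
        if u == v:
            raise ValueError("self-loops are not stored")
        if w <= 0:
            raise ValueError("edge weights must be positive")
        values[u, v] = w
        values[v, u] = w
    return build_graph(values, min_weight=0.0)


def walk_transition_probs(
    graph: ChromGraph, prev: int | None, cur: int, p: float = 1.0, q: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order transition distribution out of ``cur`` given ``prev``.

    Unnormalized score of neighbor x = weight(cur, x) * bias, where bias is
    1/p when x == prev, 1 when x neighbors prev, and 1/q otherwise.  With
    ``prev=None`` (first step) sampling is weight-proportional.  Returns
    (neighbor indices, probabilities summing to 1).
    """
    nbrs, ws = graph.neighbors(cur)
    if len(nbrs) == 0:
        raise ValueError(f"node {cur} is isolated; no transition defined")
    scores = ws.astype(np.float64).copy()
    if prev is not None:
        prev_nbrs = set(graph.neighbors(prev)[0].tolist())
        for k, x in enumerate(nbrs):
            if x == prev:
                scores[k] /= p
            elif int(x) in prev_nbrs:
                pass
            else:
                scores[k] /= q
    return nbrs, scores / scores.sum()


@dataclass
class WalkCorpus:
    """Random-walk node sequences, one row per walk."""

    walks: np.ndarray  # (n_walks, walk_length) int32
    n_nodes: int
    walk_length: int
    num_walks: int
    p: float
    q: float
    seed: int


@njit(cache=True)
def _walk_kernel(indptr, indices, weights, cumw, starts, walk_length, p, q, seed):  # pragma: no cover
    np.random.seed(seed)
    n_walks = starts.shape[0]
    walks = np.empty((n_walks, walk_length), dtype=np.int32)
    unbiased = (p == 1.0) and (q == 1.0)
    for w in range(n_walks):
        cur = starts[w]
        prev = -1
        walks[w, 0] = cur
        for step in range(1, walk_length):
            lo = indptr[cur]
            hi = indptr[cur + 1]
            if hi == lo:
                # dead end cannot happen on undirected graphs, but guard
                for rest in range(step, walk_length):
                    walks[w, rest] = cur
                break
            if unbiased or prev < 0:
                r = np.random.random() * (cumw[hi - 1] - (cumw[lo - 1] if lo > 0 else 0.0))
                base = cumw[lo - 1] if lo > 0 else 0.0
                # binary search for first k in [lo,hi) with cumw[k]-base > r
                a, b = lo, hi - 1
                while a < b:
                    mid = (a + b) // 2
                    if cumw[mid] - base > r:
                        b = mid
                    else:
                        a = mid + 1
                nxt = indices[a]
            else:
                deg = hi - lo
                scores = np.empty(deg)
                plo = indptr[prev]
                phi = indptr[prev + 1]
                total = 0.0
                for k in range(deg):
                    x = indices[lo + k]
                    s = weights[lo + k]
                    if x == prev:
                        s /= p
                    else:
                        # membership test: binary search in prev's sorted neighbors
                        a, b = plo, phi
                        found = False
                        while a < b:
                            mid = (a + b) // 2
                            if indices[mid] == x:
                                found = True
                                break
                            elif indices[mid] < x:
                                a = mid + 1
                            else:
                                b = mid
                        if not found:
                            s /= q
                    scores[k] = s
                    total += s
                r = np.random.random() * total
                acc = 0.0
                nxt = indices[hi - 1]
                for k in range(deg):
                    acc += scores[k]
                    if acc > r:
                        nxt = indices[lo + k]
                        break
            walks[w, step] = nxt
            prev = cur
            cur = nxt
    return walks


def generate_walks(
    graph: ChromGraph,
    walk_length: int = 100,
    num_walks: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> WalkCorpus:
    """Run ``num_walks`` biased walks from every non-isolated node.

    Deterministic given the seed.  Walk length counts nodes, so every walk
    visits ``walk_length`` nodes and each consecutive pair is an edge.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if walk_length < 1 or num_walks < 1:
        raise ValueError("walk_length and num_walks must be >= 1")
    non_isolated = np.flatnonzero(np.diff(graph.indptr) > 0).astype(np.int64)
    starts = np.tile(non_isolated, num_walks)
    cumw = np.cumsum(graph.weights)
    walks = _walk_kernel(
        graph.indptr,
        graph.indices,
        graph.weights.astype(np.float64),
        cumw.astype(np.float64),
        starts,
        walk_length,
        float(p),
        float(q),
        seed % (2**32),
    )
    return WalkCorpus(
        walks=walks,
        n_nodes=graph.n_nodes,
        walk_length=walk_length,
        num_walks=num_walks,
        p=p,
        q=q,
        seed=seed,
    )
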