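"""Linear transformation CNV classifiers on Hi-C row vectors.

Each bin is represented by its row of the contact matrix (its interaction
profile with every other bin).  A single linear map followed by a softmax
turns that profile into probabilities over the four CNV classes; training
minimizes the mean cross-entropy against one-hot labels by full-batch
gradient descent.  Because read counts scale linearly with copy number, a
per-chromosome model of this form separates the classes almost perfectly.

The module also hosts the dimension-reduction harness (PCA / factor
analysis / locally linear embedding) that unifies feature dimensions across
chromosomes so one weight-shared model can be trained on all of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA, FactorAnalysis
from sklearn.manifold import LocallyLinearEmbedding
from sklearn.neighbors import kneighbors_graph

from .hic_io import ContactMatrix
from .metrics import MetricsReport, compute_metrics
from .synthetic import N_CLASSES


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition of bins (default 60/40)."""

    train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0,1)")

    def indices(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Disjoint, exhaustive (train, test) index arrays over range(n)."""
        perm = np.random.default_rng(self.seed).permutation(n)
        n_train = int(round(self.train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class LinearModelParams:
    """Learned weights of the 4-class linear map ``softmax(x W + b)``."""

    W: np.ndarray
    b: np.ndarray
    feature_dim: int

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"W": self.W.tolist(), "b": self.b.tolist(), "feature_dim": self.feature_dim},
                fh,
            )

    @classmethod
    def load(cls, path) -> "LinearModelParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(W=np.asarray(d["W"]), b=np.asarray(d["b"]), feature_dim=int(d["feature_dim"]))


@dataclass
class ReducedDataset:
    """Bin features after dimension reduction, with the fitted transform."""

    features: np.ndarray
    method: str
    d: int
    fitted_transform: Any = field(repr=False, default=None)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_rows(data) -> np.ndarray:
    if isinstance(data, ContactMatrix):
        return np.asarray(data.values, dtype=np.float64)
    if isinstance(data, ReducedDataset):
        return np.asarray(data.features, dtype=np.float64)
    return np.asarray(data, dtype=np.float64)


def _train_softmax(
    X: np.ndarray, y: np.ndarray, epochs: int, lr: float, weight_decay: float
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch GD on globally rescaled features; returns weights folded
    back to the raw feature scale so prediction is ``softmax(xW + b)``.

    Features share one scalar mean/scale rather than per-feature z-scores:
    the distance-decay magnitude profile across columns is the signal that
    separates the copy-number classes, and per-feature standardization
    would erase it.  A small fixed ridge penalty curbs overfitting when the
    feature dimension exceeds the number of training bins.
    """
    mu = X.mean()
    sd = X.std()
    if sd == 0:
        sd = 1.0
    Xs = (X - mu) / sd
    n, f = Xs.shape
    Y = np.zeros((n, N_CLASSES))
    Y[np.arange(n), y] = 1.0
    W = np.zeros((f, N_CLASSES))
    b = np.zeros(N_CLASSES)
    for _ in range(epochs):
        P = _softmax(Xs @ W + b)
        G = (P - Y) / n
        W -= lr * (Xs.T @ G + weight_decay * W)
        b -= lr * G.sum(axis=0)
    W_raw = W / sd
    b_raw = b - mu * W_raw.sum(axis=0)
    return W_raw, b_raw


def fit_linear_model(
    matrix: ContactMatrix | ReducedDataset | np.ndarray,
    labels: np.ndarray,
    split: SplitSpec = SplitSpec(),
    epochs: int = 2000,
    lr: float = 0.1,
    weight_decay: float = 0.01,
) -> tuple[LinearModelParams, MetricsReport]:
    """Train a per-chromosome linear CNV classifier and score the held-out bins.

    Features are standardized internally for optimization; the returned
    parameters are folded back onto the raw feature scale.  Deterministic
    given the split seed (initialization is zero and the loss is convex).
    """
    X = _as_rows(matrix)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels length must equal the number of rows")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 bins")
    train_idx, test_idx = split.indices(X.shape[0])
    if np.unique(labels[train_idx]).size < 2:
        raise ValueError("training split contains a single class")
    W, b = _train_softmax(X[train_idx], labels[train_idx], epochs, lr, weight_decay)
    params = LinearModelParams(W=W, b=b, feature_dim=X.shape[1])
    _, probs = predict_linear(params, X[test_idx])
    return params, compute_metrics(labels[test_idx], probs)


def predict_linear(
    params: LinearModelParams, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class per row (argmax, lowest-index tie-break) plus softmax probabilities."""
    rows = np.asarray(rows, dtype=np.float64)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[1] != params.feature_dim:
        raise ValueError(
            f"feature dimension mismatch: rows have {rows.shape[1]}, "
            f"model expects {params.feature_dim}"
        )
    probs = _softmax(rows @ params.W + params.b)
    return np.argmax(probs, axis=1), probs


def reduce_dimensions(
    matrix: ContactMatrix | np.ndarray,
    method: str,
    d: int,
    n_neighbors: int | None = None,
    seed: int = 0,
) -> ReducedDataset:
    """Reduce bin row vectors to ``d`` features by PCA, FA, or LLE.

    PCA projects onto the top-d eigenvectors of the row covariance; FA fits
    a d-factor maximum-likelihood model with varimax (orthogonal) rotation;
    LLE reconstructs each bin from its k nearest neighbors and embeds
    globally.  LLE requires a connected neighbor graph and ``n_neighbors > d``
    (default ``d + 1``).
    """
    X = _as_rows(matrix)
    n = X.shape[0]
    if d >= n:
        raise ValueError(f"d={d} must be smaller than n_bins={n}")
    if d < 1:
        raise ValueError("d must be >= 1")
    if method == "pca":
        tr = PCA(n_components=d, svd_solver="full", random_state=seed)
        feats = tr.fit_transform(X)
    elif method == "fa":
        tr = FactorAnalysis(n_components=d, rotation="varimax", random_state=seed)
        feats = tr.fit_transform(X)
    elif method == "lle":
        k = n_neighbors if n_neighbors is not None else d + 1
        if k <= d:
            raise ValueError(f"lle needs n_neighbors > d (got {k} <= {d})")
        if k >= n:
            raise ValueError("n_neighbors must be < n_bins")
        knn = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
        n_comp, _ = connected_components(knn, directed=False)
        if n_comp > 1:
            raise ValueError(
                f"lle neighbor graph is disconnected ({n_comp} components)"
            )
        tr = LocallyLinearEmbedding(
            n_neighbors=k, n_components=d, random_state=seed
        )
        feats = tr.fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r} (expected pca, fa, or lle)")
    if np.isnan(feats).any():
        raise ValueError(f"{method} produced NaN features")
    return ReducedDataset(features=feats, method=method, d=d, fitted_transform=tr)


def fit_shared_linear(
    datasets: list[tuple[ReducedDataset, np.ndarray]],
    split: SplitSpec = SplitSpec(),
    epochs: int = 2000,
    lr: float = 0.1,
    weight_decay: float = 0.01,
) -> tuple[LinearModelParams, dict[str, MetricsReport]]:
    """Train one weight-shared linear model on the pooled train splits of
    several chromosomes (all reduced to the same dimension).

    Returns the shared parameters and per-chromosome reports plus a
    ``"pooled"`` report over all held-out bins.  Each chromosome gets its
    own split derived from ``split.seed + index``.
    """
    if not datasets:
        raise ValueError("datasets must be non-empty")
    dims = {ds.d for ds, _ in datasets}
    if len(dims) > 1:
        raise ValueError(f"mixed feature dimensions across chromosomes: {sorted(dims)}")
    methods = {ds.method for ds, _ in datasets}
    if len(methods) > 1:
        raise ValueError(f"mixed reduction methods: {sorted(methods)}")

    splits = []
    X_train, y_train = [], []
    for k, (ds, labels) in enumerate(datasets):
        labels = np.asarray(labels)
        sub = SplitSpec(train_fraction=split.train_fraction, seed=split.seed + k)
        tr_idx, te_idx = sub.indices(ds.features.shape[0])
        splits.append((tr_idx, te_idx))
        X_train.append(ds.features[tr_idx])
        y_train.append(labels[tr_idx])
    X_pool = np.vstack(X_train)
    y_pool = np.concatenate(y_train)
    if np.unique(y_pool).size < 2:
        raise ValueError("pooled training split contains a single class")
    W, b = _train_softmax(X_pool, y_pool, epochs, lr, weight_decay)
    params = LinearModelParams(W=W, b=b, feature_dim=X_pool.shape[1])

    reports: dict[str, MetricsReport] = {}
    all_true, all_probs = [], []
    for k, ((ds, labels), (tr_idx, te_idx)) in enumerate(zip(datasets, splits)):
        labels = np.asarray(labels)
        _, probs = predict_linear(params, ds.features[te_idx])
        reports[f"chrom{k}"] = compute_metrics(labels[te_idx], probs)
        all_true.append(labels[te_idx])
        all_probs.append(probs)
    reports["pooled"] = compute_metrics(np.concatenate(all_true), np.vstack(all_probs))
    return params, reports
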