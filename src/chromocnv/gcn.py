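"""Four-layer residual GCN for per-bin CNV classification.

The network propagates node2vec features through the symmetric-normalized
weighted adjacency Â = D̃^(-1/2)(W + I)D̃^(-1/2):

    H1 = tanh(Â X W1)
    H2 = tanh(Â H1 W2)
    H3 = tanh(Â H2 W3)
    H4 = tanh(Â (H1 + H3) W4)        # residual: H1 is re-injected
    O  = sigmoid(dropout(H4) W5 + b5)

The head is a per-class sigmoid scored with per-class cross-entropy against
one-hot labels (the gradient at the logits is then O - Y, as for softmax).
Training is full-batch Adam on a random 60% of nodes; the rest are held out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ChromGraph
from .linear import SplitSpec
from .metrics import MetricsReport, compute_metrics
from .synthetic import N_CLASSES


@dataclass
class GCNParams:
    """Learnable weights of the 4-layer GCN plus dense head."""

    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    W4: np.ndarray
    W5: np.ndarray
    b5: np.ndarray
    dropout_rate: float = 0.5
    hidden_dim: int = 64

    @classmethod
    def init(cls, feature_dim: int, hidden_dim: int = 64, dropout_rate: float = 0.5,
             seed: int = 0) -> "GCNParams":
        rng = np.random.default_rng(seed)

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)

        h = hidden_dim
        return cls(
            W1=glorot(feature_dim, h),
            W2=glorot(h, h),
            W3=glorot(h, h),
            W4=glorot(h, h),
            W5=glorot(h, N_CLASSES),
            b5=np.zeros(N_CLASSES, dtype=np.float32),
            dropout_rate=dropout_rate,
            hidden_dim=h,
        )

    def copy(self) -> "GCNParams":
        return GCNParams(
            W1=self.W1.copy(), W2=self.W2.copy(), W3=self.W3.copy(),
            W4=self.W4.copy(), W5=self.W5.copy(), b5=self.b5.copy(),
            dropout_rate=self.dropout_rate, hidden_dim=self.hidden_dim,
        )

    def arrays(self) -> list[np.ndarray]:
        return [self.W1, self.W2, self.W3, self.W4, self.W5, self.b5]

    def save(self, path) -> None:
        np.savez(path, **{f"arr{k}": a for k, a in enumerate(self.arrays())},
                 dropout_rate=self.dropout_rate, hidden_dim=self.hidden_dim)

    @classmethod
    def load(cls, path) -> "GCNParams":
        with np.load(path) as z:
            return cls(
                W1=z["arr0"], W2=z["arr1"], W3=z["arr2"], W4=z["arr3"],
                W5=z["arr4"], b5=z["arr5"],
                dropout_rate=float(z["dropout_rate"]),
                hidden_dim=int(z["hidden_dim"]),
            )


@dataclass(frozen=True)
class TrainConfig:
    """Full-batch Adam training schedule for the GCN."""

    split: SplitSpec = SplitSpec(train_fraction=0.6, seed=0)
    epochs: int = 200
    lr: float = 0.01
    seed: int = 0
    hidden_dim: int = 64
    dropout_rate: float = 0.5
    betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def normalize_adjacency(graph: ChromGraph) -> np.ndarray:
    """Symmetric-normalized propagation operator with unit self-loops.

    Â = D̃^(-1/2) (W + I) D̃^(-1/2); isolated nodes get Â_ii = 1.
    """
    n = graph.n_nodes
    A = np.zeros((n, n), dtype=np.float64)
    for u in range(n):
        nbrs, ws = graph.neighbors(u)
        A[u, nbrs] = ws
    A[np.diag_indices(n)] += 1.0
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return (A * dinv[:, None] * dinv[None, :]).astype(np.float32)


def _forward(params: GCNParams, prop: np.ndarray, X: np.ndarray,
             dropout_mask: np.ndarray | None):
    """Forward pass returning output probabilities and cached activations."""
    AX = prop @ X
    H1 = np.tanh(AX @ params.W1)
    AH1 = prop @ H1
    H2 = np.tanh(AH1 @ params.W2)
    AH2 = prop @ H2
    H3 = np.tanh(AH2 @ params.W3)
    R = H1 + H3
    AR = prop @ R
    H4 = np.tanh(AR @ params.W4)
    H4d = H4 if dropout_mask is None else H4 * dropout_mask
    logits = H4d @ params.W5 + params.b5
    O = 1.0 / (1.0 + np.exp(-logits))
    cache = (AX, H1, AH1, H2, AH2, H3, AR, H4, H4d)
    return O, cache


def gcn_forward(
    params: GCNParams,
    prop: np.ndarray,
    features,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_hidden: bool = False,
):
    """Per-bin CNV class probabilities O in (0,1)^4.

    Dropout on H4 (inverted scaling) is applied only when ``training`` is
    set, using ``rng``.  With ``return_hidden`` the last convolutional
    activation H4 is returned as well (used for 2-D visualization).
    Float inputs keep their precision (float64 in, float64 math).
    """
    X = np.asarray(getattr(features, "vectors", features))
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float32)
    if prop.shape[0] != prop.shape[1] or prop.shape[0] != X.shape[0]:
        raise ValueError("propagation matrix and features disagree on n_nodes")
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match W1 input {params.W1.shape[0]}"
        )
    mask = None
    if training and params.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        keep = 1.0 - params.dropout_rate
        mask = (rng.random(size=(X.shape[0], params.hidden_dim)) < keep) / keep
        mask = mask.astype(np.float32)
    O, cache = _forward(params, prop, X, mask)
    if return_hidden:
        return O, cache[7]
    return O


def _bce_loss(O: np.ndarray, Y: np.ndarray, rows: np.ndarray) -> float:
    eps = 1e-7
    o = np.clip(O[rows].astype(np.float64), eps, 1 - eps)
    y = Y[rows]
    return float(np.mean(np.sum(-y * np.log(o) - (1 - y) * np.log(1 - o), axis=1)))


class _Adam:
    def __init__(self, shapes, lr, betas):
        self.lr = lr
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float32) for s in shapes]

    def step(self, params_arrays, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, (p, g) in enumerate(zip(params_arrays, grads)):
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _train_steps(
    params: GCNParams,
    prop: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    train_rows: np.ndarray,
    epochs: int,
    lr: float,
    betas: tuple[float, float],
    rng: np.random.Generator,
) -> list[float]:
    """Full-batch Adam; mutates ``params`` in place, returns the loss curve."""
    n = X.shape[0]
    keep = 1.0 - params.dropout_rate
    opt = _Adam([a.shape for a in params.arrays()], lr, betas)
    losses = []
    row_mask = np.zeros((n, 1), dtype=np.float32)
    row_mask[train_rows] = 1.0
    n_train = len(train_rows)
    for _ in range(epochs):
        if params.dropout_rate > 0:
            mask = ((rng.random(size=(n, params.hidden_dim)) < keep) / keep).astype(np.float32)
        else:
            mask = None
        O, cache = _forward(params, prop, X, mask)
        AX, H1, AH1, H2, AH2, H3, AR, H4, H4d = cache
        losses.append(_bce_loss(O, Y, train_rows))
        dL = (O - Y) * row_mask / n_train  # grad at logits, train rows only
        gW5 = H4d.T @ dL
        gb5 = dL.sum(axis=0)
        dH4 = dL @ params.W5.T
        if mask is not None:
            dH4 = dH4 * mask
        dZ4 = dH4 * (1.0 - H4 * H4)
        gW4 = AR.T @ dZ4
        dR = prop @ (dZ4 @ params.W4.T)
        dH3 = dR
        dZ3 = dH3 * (1.0 - H3 * H3)
        gW3 = AH2.T @ dZ3
        dH2 = prop @ (dZ3 @ params.W3.T)
        dZ2 = dH2 * (1.0 - H2 * H2)
        gW2 = AH1.T @ dZ2
        dH1 = dR + prop @ (dZ2 @ params.W2.T)
        dZ1 = dH1 * (1.0 - H1 * H1)
        gW1 = AX.T @ dZ1
        opt.step(params.arrays(), [gW1, gW2, gW3, gW4, gW5, gb5])
    return losses


def _one_hot(labels: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(labels), N_CLASSES), dtype=np.float32)
    Y[np.arange(len(labels)), labels] = 1.0
    return Y


def train_gcn(
    graph: ChromGraph,
    features,
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[GCNParams, MetricsReport, list[float]]:
    """Train the residual GCN on 60% of the (non-isolated) bins.

    Returns the trained parameters, held-out metrics on the remaining bins,
    and the per-epoch training-loss curve.  Reproducible under the config
    seeds (split seed, init/dropout seed).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_nodes:
        raise ValueError("labels length must equal the number of nodes")
    X = np.asarray(getattr(features, "vectors", features), dtype=np.float32)
    prop = normalize_adjacency(graph)
    usable = np.setdiff1d(np.arange(graph.n_nodes), graph.isolated_nodes)
    tr_loc, te_loc = config.split.indices(len(usable))
    train_rows = usable[tr_loc]
    test_rows = usable[te_loc]
    if np.unique(labels[train_rows]).size < 2:
        raise ValueError("training split contains a single class")
    params = GCNParams.init(
        feature_dim=X.shape[1],
        hidden_dim=config.hidden_dim,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
    )
    rng = np.random.default_rng(config.seed + 1)
    Y = _one_hot(labels)
    losses = _train_steps(
        params, prop, X, Y, train_rows, config.epochs, config.lr, config.betas, rng
    )
    O = gcn_forward(params, prop, X, training=False)
    report = compute_metrics(labels[test_rows], O[test_rows])
    return params, report, losses


def predict_gcn(params: GCNParams, graph: ChromGraph, features) -> tuple[np.ndarray, np.ndarray]:
    """Inference over all nodes: (argmax labels, probability matrix)."""
    prop = normalize_adjacency(graph)
    O = gcn_forward(params, prop, features, training=False)
    return np.argmax(O, axis=1), O


def fine_tune(
    params: GCNParams,
    target_graph: ChromGraph,
    target_features,
    target_labels: np.ndarray,
    label_fraction: float = 0.02,
    epochs: int = 5,
    lr: float = 0.05,
    seed: int = 0,
) -> tuple[GCNParams, MetricsReport]:
    """Transfer a trained GCN to a new chromosome with few labels.

    Continues optimization (fresh Adam state, larger step size) using only
    a random ``label_fraction`` of target nodes as supervision, then
    evaluates on all remaining non-isolated target nodes.  Only a handful
    of epochs are needed because the source model already encodes the
    structure-to-CNV mapping.
    """
    if not (0.0 < label_fraction < 1.0):
        raise ValueError("label_fraction must be in (0,1)")
    target_labels = np.asarray(target_labels)
    X = np.asarray(getattr(target_features, "vectors", target_features), dtype=np.float32)
    usable = np.setdiff1d(np.arange(target_graph.n_nodes), target_graph.isolated_nodes)
    rng = np.random.default_rng(seed)
    n_lab = max(1, int(round(label_fraction * len(usable))))
    perm = rng.permutation(len(usable))
    lab_rows = usable[perm[:n_lab]]
    eval_rows = usable[perm[n_lab:]]
    if np.unique(target_labels[lab_rows]).size < 2:
        raise ValueError(
            f"fine-tuning sample of {n_lab} nodes covers a single class; "
            "increase label_fraction"
        )
    tuned = params.copy()
    prop = normalize_adjacency(target_graph)
    Y = _one_hot(target_labels)
    _train_steps(tuned, prop, X, Y, lab_rows, epochs, lr, (0.9, 0.999),
                 np.random.default_rng(seed + 1))
    O = gcn_forward(tuned, prop, X, training=False)
    report = compute_metrics(target_labels[eval_rows], O[eval_rows])
    return tuned, report


def evaluate_zero_shot(
    params: GCNParams, graph: ChromGraph, features, labels: np.ndarray
) -> MetricsReport:
    """Score a trained GCN on a new chromosome without any fine-tuning."""
    labels = np.asarray(labels)
    usable = np.setdiff1d(np.arange(graph.n_nodes), graph.isolated_nodes)
    prop = normalize_adjacency(graph)
    O = gcn_forward(params, prop, features, training=False)
    return compute_metrics(labels[usable], O[usable])
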