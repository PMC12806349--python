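"""Classification metrics for per-bin CNV predictions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score

from .synthetic import N_CLASSES


@dataclass
class MetricsReport:
    """Held-out performance of a 4-class CNV classifier.

    ``accuracy`` is the fraction of bins whose argmax prediction matches the
    truth; ``f1_macro`` and ``auc_macro`` (one-vs-rest) average only over
    classes present in the truth vector.  ``confusion`` is the full 4x4
    count matrix (rows = truth, columns = prediction).
    """

    accuracy: float
    f1_macro: float
    auc_macro: float
    per_class: dict = field(repr=False)
    confusion: np.ndarray = field(repr=False)
    n_test: int = 0

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_percent": self.accuracy_percent,
            "f1_macro": self.f1_macro,
            "auc_macro": self.auc_macro,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
        }


def predict_from_probs(probs: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties broken toward the lowest class index."""
    return np.argmax(probs, axis=1)


def compute_metrics(true: np.ndarray, probs: np.ndarray) -> MetricsReport:
    """Score per-bin class probabilities against true labels.

    AUC is computed one-vs-rest per class and macro-averaged over the
    classes actually present in ``true`` (a class absent from the truth has
    no positives, so its ROC curve is undefined and it is skipped, with the
    average renormalized over the remaining classes).
    """
    true = np.asarray(true)
    probs = np.asarray(probs, dtype=np.float64)
    if true.shape[0] != probs.shape[0]:
        raise ValueError(
            f"length mismatch: {true.shape[0]} labels vs {probs.shape[0]} probability rows"
        )
    if probs.ndim != 2 or probs.shape[1] != N_CLASSES:
        raise ValueError(f"probs must be n x {N_CLASSES}")
    if not np.isfinite(probs).all():
        raise ValueError("probs contain non-finite entries")
    pred = predict_from_probs(probs)
    present = np.unique(true)
    conf = confusion_matrix(true, pred, labels=np.arange(N_CLASSES))
    accuracy = float(np.trace(conf)) / float(conf.sum())

    prec, rec, f1, support = precision_recall_fscore_support(
        true, pred, labels=present, average=None, zero_division=0
    )
    f1_macro = float(f1.mean())

    aucs = []
    per_class: dict[int, dict[str, float]] = {}
    for k, cls in enumerate(present):
        entry = {
            "precision": float(prec[k]),
            "recall": float(rec[k]),
            "f1": float(f1[k]),
            "support": int(support[k]),
        }
        is_cls = (true == cls).astype(int)
        if 0 < is_cls.sum() < len(true):
            auc = float(roc_auc_score(is_cls, probs[:, cls]))
            entry["auc"] = auc
            aucs.append(auc)
        per_class[int(cls)] = entry
    auc_macro = float(np.mean(aucs)) if aucs else float("nan")

    return MetricsReport(
        accuracy=accuracy,
        f1_macro=f1_macro,
        auc_macro=auc_macro,
        per_class=per_class,
        confusion=conf,
        n_test=int(len(true)),
    )


def embed_pca_2d(features: np.ndarray) -> np.ndarray:
    """Project row features onto their top-2 principal components.

    Used to visualize the structure of GCN hidden features; raises on
    constant input (no variance to decompose).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("features must be n x d with d >= 2")
    centered = features - features.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("constant features: PCA undefined")
    return PCA(n_components=2, svd_solver="full").fit_transform(features)
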