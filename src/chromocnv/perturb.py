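"""Five perturbation operators probing what the GCN actually learns.

Two act on labels (reconstruction, shuffling) and three on the contact
matrix (row shuffling, value shuffling, Gaussian value noise).  Each is a
pure function of (input, seed) and reports what fraction of the data it
left unchanged, since an apparently mild accuracy drop can simply mean the
perturbation barely changed anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import ContactMatrix
from .synthetic import N_CLASSES


@dataclass(frozen=True)
class PerturbationReport:
    """Bookkeeping for one perturbation run."""

    kind: str
    seed: int
    fraction_unchanged: float


KINDS = ("label_reconstruction", "label_shuffle", "row_shuffle", "value_shuffle", "value_noise")


def reconstruct_labels(n_bins: int, seed: int) -> np.ndarray:
    """Replace every label by an i.i.d. uniform draw over the 4 classes."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return np.random.default_rng(seed).integers(0, N_CLASSES, size=n_bins)


def shuffle_labels(labels: np.ndarray, seed: int) -> tuple[np.ndarray, PerturbationReport]:
    """Uniform random permutation of the label vector (multiset preserved)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    shuffled = labels[rng.permutation(len(labels))]
    frac = float(np.mean(shuffled == labels))
    return shuffled, PerturbationReport("label_shuffle", seed, frac)


def shuffle_rows(matrix: ContactMatrix, seed: int) -> tuple[np.ndarray, PerturbationReport]:
    """Permute whole rows of the matrix; columns and labels stay in place.

    Returns the raw permuted array (generally asymmetric); use
    :func:`as_graph_input` before graph construction.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.n_bins)
    out = matrix.values[perm]
    frac = float(np.mean(out == matrix.values))
    return out, PerturbationReport("row_shuffle", seed, frac)


def shuffle_values(matrix: ContactMatrix, seed: int) -> tuple[np.ndarray, PerturbationReport]:
    """Flatten, permute all n^2 cells uniformly, reshape back."""
    rng = np.random.default_rng(seed)
    flat = matrix.values.ravel()
    out = flat[rng.permutation(flat.size)].reshape(matrix.values.shape)
    frac = float(np.mean(out == matrix.values))
    return out, PerturbationReport("value_shuffle", seed, frac)


def add_value_noise(
    matrix: ContactMatrix, seed: int, mean: float = 0.0, sd: float = 1.0
) -> np.ndarray:
    """Add one independent Gaussian draw to every cell.

    The returned array may contain small negatives; they are floored at 0
    only when the matrix is turned into a graph (:func:`as_graph_input`).
    """
    rng = np.random.default_rng(seed)
    return matrix.values + rng.normal(mean, sd, size=matrix.values.shape)


def as_graph_input(values: np.ndarray, chrom: str = "chrP", bin_size: int = 40_000) -> ContactMatrix:
    """Make a perturbed array consumable by the graph pipeline.

    Row- and value-shuffled matrices are generally asymmetric while the
    chromosomal graph is undirected, so the array is symmetrized as
    (M + Mᵀ)/2; negative cells (possible after Gaussian noise) are floored
    at 0 because edge weights must be positive.
    """
    values = np.asarray(values, dtype=np.float64)
    sym = np.clip((values + values.T) / 2.0, 0.0, None)
    return ContactMatrix(values=sym, chrom=chrom, bin_size=bin_size)


def apply_perturbation(
    kind: str,
    matrix: ContactMatrix,
    labels: np.ndarray,
    seed: int,
    noise_mean: float = 0.0,
    noise_sd: float = 1.0,
) -> tuple[ContactMatrix, np.ndarray, PerturbationReport]:
    """Dispatch one of the five operators; returns pipeline-ready
    (matrix, labels, report)."""
    if kind == "label_reconstruction":
        new = reconstruct_labels(matrix.n_bins, seed)
        frac = float(np.mean(new == np.asarray(labels)))
        return matrix, new, PerturbationReport(kind, seed, frac)
    if kind == "label_shuffle":
        new, report = shuffle_labels(labels, seed)
        return matrix, new, report
    if kind == "row_shuffle":
        values, report = shuffle_rows(matrix, seed)
        return as_graph_input(values, matrix.chrom, matrix.bin_size), labels, report
    if kind == "value_shuffle":
        values, report = shuffle_values(matrix, seed)
        return as_graph_input(values, matrix.chrom, matrix.bin_size), labels, report
    if kind == "value_noise":
        values = add_value_noise(matrix, seed, noise_mean, noise_sd)
        report = PerturbationReport(kind, seed, float(np.mean(values == matrix.values)))
        return as_graph_input(values, matrix.chrom, matrix.bin_size), labels, report
    raise ValueError(f"unknown perturbation kind {kind!r}; expected one of {KINDS}")
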