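"""Contact-matrix I/O, resolution coarsening, and ICE matrix balancing.

Two plain-text matrix dialects are supported: dense whitespace/tab separated
(one row per line, no header) and sparse triplet lines ``bin_i  bin_j  count``
(0-based, upper triangle).  Per-bin labels travel as BED-like text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SYM_RTOL = 1e-8


@dataclass
class ContactMatrix:
    """Symmetric non-negative intra-chromosomal contact map at fixed bin size."""

    values: np.ndarray
    chrom: str = "chr1"
    bin_size: int = 40_000

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"non-square matrix of shape {v.shape}")
        if np.isnan(v).any():
            raise ValueError("matrix contains NaN")
        if (v < 0).any():
            raise ValueError("matrix contains negative counts")
        scale = max(float(np.abs(v).max()), 1.0)
        asym = np.abs(v - v.T)
        if asym.max() > _SYM_RTOL * scale:
            i, j = np.unravel_index(int(np.argmax(asym)), v.shape)
            raise ValueError(
                f"asymmetry beyond tolerance at cell ({i},{j}): "
                f"{v[i, j]!r} vs {v[j, i]!r}"
            )


@dataclass
class BalancingResult:
    """Outcome of ICE balancing: normalized matrix plus per-bin biases.

    ``biases`` multiply as ``normalized_ij == values_ij / (bias_i * bias_j)``
    for retained bins; all-zero (masked) bins carry NaN as a sentinel.
    """

    normalized: ContactMatrix
    biases: np.ndarray
    n_iterations: int
    converged: bool


def write_contact_matrix(path, matrix: ContactMatrix, format: str = "dense") -> None:
    """Write a matrix as dense TSV or upper-triangle triplet text.

    Dense output uses %.17g so float round-trips are bit-exact.
    """
    if format == "dense":
        np.savetxt(path, matrix.values, fmt="%.17g", delimiter="\t")
    elif format == "triplet":
        v = matrix.values
        iu, ju = np.nonzero(np.triu(v))
        with open(path, "w") as fh:
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{v[i, j]:.17g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_contact_matrix(
    path,
    format: str = "dense",
    n_bins: int | None = None,
    chrom: str = "chr1",
    bin_size: int = 40_000,
) -> ContactMatrix:
    """Load a contact matrix from dense TSV or sparse triplet text.

    Triplet input is mirrored onto the lower triangle; ``n_bins`` may be
    given explicitly, otherwise it is inferred as ``max index + 1``.
    Dense input is validated for squareness, sign, and symmetry.
    """
    if format == "dense":
        values = np.loadtxt(path, ndmin=2)
        if values.shape[0] != values.shape[1]:
            raise ValueError(
                f"non-square dense matrix: {values.shape[0]} rows x "
                f"{values.shape[1]} columns"
            )
        m = ContactMatrix(values=values, chrom=chrom, bin_size=bin_size)
        m.validate()
        return m
    if format == "triplet":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            raise ValueError("empty triplet file")
        if data.shape[1] != 3:
            raise ValueError("triplet lines must have 3 fields: i j count")
        ii = data[:, 0].astype(np.int64)
        jj = data[:, 1].astype(np.int64)
        cc = data[:, 2]
        if (ii < 0).any() or (jj < 0).any():
            raise ValueError("negative bin index in triplet input")
        if (cc < 0).any():
            raise ValueError("negative count in triplet input")
        n = n_bins if n_bins is not None else int(max(ii.max(), jj.max())) + 1
        values = np.zeros((n, n))
        values[ii, jj] = cc
        off = ii != jj
        values[jj[off], ii[off]] = cc[off]
        m = ContactMatrix(values=values, chrom=chrom, bin_size=bin_size)
        m.validate()
        return m
    raise ValueError(f"unknown format {format!r}")


def coarsen_resolution(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum factor x factor blocks into coarser bins; total count is conserved.

    A trailing partial block is summed as-is.
    """
    if factor <= 0:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ContactMatrix(
            values=matrix.values.copy(), chrom=matrix.chrom, bin_size=matrix.bin_size
        )
    n = matrix.n_bins
    starts = np.arange(0, n, factor)
    coarse = np.add.reduceat(np.add.reduceat(matrix.values, starts, axis=0), starts, axis=1)
    return ContactMatrix(values=coarse, chrom=matrix.chrom, bin_size=matrix.bin_size * factor)


def ice_normalize(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> BalancingResult:
    """Iterative correction (ICE) balancing of a contact matrix.

    Repeatedly rescales per-bin biases by each bin's relative coverage and
    divides the matrix by the bias outer product until retained row sums
    agree within ``tol`` (max relative deviation from the mean).  All-zero
    bins are masked out of the iteration and returned untouched, with NaN
    bias.
    """
    matrix.validate()
    if tol <= 0:
        raise ValueError("tol must be > 0")
    v = matrix.values.astype(np.float64).copy()
    n = v.shape[0]
    retained = v.sum(axis=1) > 0
    if not retained.any():
        raise ValueError("every row is zero; nothing to balance")
    sub = v[np.ix_(retained, retained)]
    biases = np.ones(int(retained.sum()))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = sub.sum(axis=1)
        mean = s.mean()
        if np.max(np.abs(s - mean)) / mean < tol:
            converged = True
            break
        f = s / mean
        biases *= f
        sub /= np.outer(f, f)
    out = matrix.values.astype(np.float64).copy()
    out[np.ix_(retained, retained)] = sub
    full_biases = np.full(n, np.nan)
    full_biases[retained] = biases
    normalized = ContactMatrix(values=out, chrom=matrix.chrom, bin_size=matrix.bin_size)
    return BalancingResult(
        normalized=normalized, biases=full_biases, n_iterations=n_iter, converged=converged
    )


# ---------------------------------------------------------------------------
# BED-like per-bin label files: chrom  start_bp  end_bp  copy_number  label


def write_labels(
    path, labels: np.ndarray, copy_numbers: np.ndarray | None = None,
    chrom: str = "chrS", bin_size: int = 40_000,
) -> None:
    from .synthetic import LABEL_NAMES

    labels = np.asarray(labels)
    if copy_numbers is None:
        # representative copy number per class: 1, 2, 3, 4
        copy_numbers = np.array([1, 2, 3, 4])[labels]
    with open(path, "w") as fh:
        for b, (lab, cn) in enumerate(zip(labels, copy_numbers)):
            fh.write(
                f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{int(cn)}\t"
                f"{LABEL_NAMES[int(lab)]}\n"
            )


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Read per-bin labels; returns (class codes, copy numbers)."""
    from .synthetic import LABEL_NAMES

    name_to_code = {name: k for k, name in enumerate(LABEL_NAMES)}
    labels, cns = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"malformed label line: {line!r}")
            cns.append(int(fields[3]))
            labels.append(name_to_code[fields[4]])
    return np.asarray(labels, dtype=np.int64), np.asarray(cns, dtype=np.int64)
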