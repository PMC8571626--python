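"""Bray–Curtis dissimilarity and principal coordinates analysis.

Distance matrices are carried as :class:`skbio.DistanceMatrix` (labelled,
symmetric, hollow).  Bray–Curtis is computed on whatever scale the table
carries; the pipeline applies it to compositionally transformed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = ["bray_curtis", "pcoa", "PCoAResult",
           "write_distance_matrix", "read_distance_matrix"]


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    BC(x, y) = 1 − 2·Σ min(xᵢ, yᵢ) / (Σ xᵢ + Σ yᵢ), in [0, 1] for
    non-negative data.  All-zero samples are rejected (the dissimilarity is
    undefined for them).
    """
    sums = table.values.sum(axis=0)
    zero = [sid for sid, s in zip(table.sample_ids, sums) if s == 0]
    if zero:
        raise ValueError(f"Bray–Curtis undefined for all-zero samples: {zero[:5]}")
    condensed = pdist(table.values.T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a distance matrix.

    ``eigenvalues`` includes negative values (reported, not corrected);
    coordinates on non-positive axes are zero.  ``proportion_explained`` is
    relative to the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int) -> PCoAResult:
    """Principal coordinates analysis by Gower-centred eigendecomposition.

    The matrix of squared distances is double-centred, eigendecomposed, and
    coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues, sorted by decreasing eigenvalue.  Negative eigenvalues (from
    non-Euclidean dissimilarities such as Bray–Curtis) are reported unchanged
    but contribute zero coordinates.
    """
    n = dm.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n - 1:
        raise ValueError(f"k must be <= n-1 = {n - 1}, got {k}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    centered = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centered @ d2 @ centered
    eigvals, eigvecs = eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigvals[axis] > 0:
            coords[:, axis] = eigvecs[:, axis] * np.sqrt(eigvals[axis])
    positive_sum = eigvals[eigvals > 0].sum()
    proportion = np.where(eigvals > 0, eigvals, 0.0) / positive_sum \
        if positive_sum > 0 else np.zeros(n)
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{i + 1}" for i in range(k)])
    return PCoAResult(coordinates=frame, eigenvalues=eigvals,
                      proportion_explained=proportion)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Serialise as a labelled square TSV."""
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
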