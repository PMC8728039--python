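"""Population structure: Euclidean genetic distances and PCoA.

Classical (metric) multidimensional scaling of the Euclidean distance
matrix computed on allele dosages.  For an exact Euclidean input this is
identical, axis by axis, to principal components of the centered dosage
matrix; percent variance explained is reported over the positive
eigenvalues only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per retained axis, % of positive-eigenvalue sum


def euclidean_distance_matrix(dm) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples on their dosage vectors."""
    if dm.has_missing():
        raise ValueError(
            "dosage matrix contains missing entries; run qc.impute_mode first"
        )
    d = squareform(pdist(dm.dosages.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(dm.sample_ids, d)


def pcoa(dist: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical scaling: double-center -D^2/2, eigendecompose, scale by
    sqrt(eigenvalue).

    Negative eigenvalues (numerically possible) are excluded from the
    percent-variance denominator.  Each axis's sign is fixed by making its
    largest-magnitude coordinate positive, so output is reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dist.values
    n = D.shape[0]
    B = -0.5 * D**2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(np.abs(eigval[0]), 1.0) * 1e-10
    positive = eigval > tol
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    pos_sum = eigval[positive].sum()
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    # reproducible sign: largest-|coordinate| entry positive per axis
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    pct = 100.0 * eigval[:k] / pos_sum
    frame = pd.DataFrame(
        coords, index=dist.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return PCoAResult(coordinates=frame, eigenvalues=eigval, pct_variance=pct)


def pcoa_table(result: PCoAResult, sample_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scatter-ready coordinate table with generation/family labels joined."""
    out = result.coordinates.copy()
    if sample_meta is not None:
        out = out.join(sample_meta)
    return out
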