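"""Embedding-space analytics: classical MDS, Procrustes alignment, and
hierarchical clustering of a similarity matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import squareform

from .errors import DataError, ParameterError
from .similarity import SimilarityMatrix


@dataclass
class Configuration:
    """A centered low-dimensional coordinate layout of the items, with the
    eigenvalue diagnostics of the embedding step."""

    items: list
    coords: np.ndarray
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.coords = self.coords - self.coords.mean(axis=0, keepdims=True)


def similarity_to_distance(s: SimilarityMatrix) -> np.ndarray:
    """Bridge a similarity matrix to distances for MDS/clustering.

    Embedding-derived (Gram) similarities use the induced Euclidean
    metric d_ij = sqrt(S_ii + S_jj - 2 S_ij); rating-derived similarities
    on the 0-100 scale use the complement d_ij = 100 - S_ij.
    """
    v = s.values
    if s.source.startswith("rating"):
        d = 100.0 - v
        np.fill_diagonal(d, 0.0)
        if d.min() < -1e-9:
            raise DataError("rating similarities above 100 produce negative distances")
        return np.maximum(d, 0.0)
    sq = np.diag(v)[:, None] + np.diag(v)[None, :] - 2.0 * v
    if sq.min() < -1e-9:
        raise DataError("matrix is not a valid Gram matrix (negative squared distances)")
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(d: np.ndarray, m: int = 3, items: list | None = None) -> Configuration:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, takes the top-m
    eigenpairs, and scales eigenvectors by the square roots of their
    eigenvalues.  Negative eigenvalues (non-Euclidean input) are truncated
    to zero coordinates but reported in the diagnostics.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or np.abs(d - d.T).max() > 1e-9:
        raise DataError("distance matrix must be square and symmetric")
    if m < 1 or m > n:
        raise ParameterError(f"m must be in [1, {n}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top = eigvals[:m]
    coords = eigvecs[:, :m] * np.sqrt(np.maximum(top, 0.0))
    return Configuration(
        items=items if items is not None else list(range(n)),
        coords=coords,
        eigenvalues=eigvals,
    )


def procrustes_align(x: Configuration, y: Configuration) -> tuple[Configuration, float]:
    """Align configuration y onto x by optimal translation,
    rotation/reflection, and isotropic scaling.

    Returns the aligned copy of y (in x's frame) and the disparity: the
    residual sum of squares after alignment, normalized to [0, 1]
    (0 = perfect match after similarity transform)."""
    X = x.coords - x.coords.mean(axis=0)
    Y = y.coords - y.coords.mean(axis=0)
    if X.shape != Y.shape:
        raise DataError("configurations must have matching shapes")
    nx = np.linalg.norm(X)
    ny = np.linalg.norm(Y)
    if nx == 0 or ny == 0:
        raise DataError("degenerate (all-coincident) configuration")
    Xs, Ys = X / nx, Y / ny
    R, s = orthogonal_procrustes(Ys, Xs)
    disparity = float(1.0 - s**2)  # residual of unit-norm configs after scaling by s
    aligned = (Ys @ R) * s * nx + x.coords.mean(axis=0)
    return Configuration(items=list(y.items), coords=aligned), max(disparity, 0.0)


def hierarchical_cluster(
    d: np.ndarray, k: int = 3, items: list | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering with weighted-average (WPGMA) linkage.

    Returns the scipy linkage matrix and the 0-based labels from cutting
    the tree at ``k`` clusters (default 3, the number of main visual
    modes the pipeline's analyses group samples into)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}]")
    condensed = squareform(d, checks=True)
    linkage = hierarchy.linkage(condensed, method="weighted")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust") - 1
    return linkage, labels
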