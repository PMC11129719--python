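"""Pairwise similarity matrices and their comparison.

Two representations of the same items are bridged here: similarity
derived from a triplet embedding (Gram form, or an average choice
probability), and similarity derived from attribute ratings on the 0-100
scale (100 minus the absolute rating difference per attribute; the joint
matrix is the entrywise root mean square over attributes).  Matrices are
compared by Pearson correlation over the vectorized upper triangle,
conventionally excluding the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import pearsonr

from .errors import DataError, ParameterError
from .vice_embedding import Embedding


@dataclass
class SimilarityMatrix:
    items: list
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.items):
            raise DataError("similarity matrix must be square and match item labels")
        if np.abs(v - v.T).max() > 1e-9:
            raise DataError("similarity matrix must be symmetric to 1e-9")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, items: list) -> "SimilarityMatrix":
        idx = [self.items.index(i) for i in items]
        return SimilarityMatrix(
            items=list(items), values=self.values[np.ix_(idx, idx)], source=self.source
        )


def sim_from_embedding(emb: Embedding, mode: str = "dot") -> SimilarityMatrix:
    """Similarity matrix of an embedding.

    ``dot``: the Gram matrix S_ij = x_i . x_j (diagonal = squared loading
    norms).  ``choice_prob``: S_ij = the target-matching probability that
    the pair (i, j) is preferred over an alternative third item, averaged
    over all third items k and over which of i/j plays the target role.
    """
    if emb.d == 0:
        raise ParameterError("embedding has zero dimensions")
    x = emb.loadings
    gram = x @ x.T
    if mode == "dot":
        return SimilarityMatrix(items=list(emb.items), values=gram, source="embedding")
    if mode != "choice_prob":
        raise ParameterError(f"unknown similarity mode {mode!r}")
    n = emb.n_items
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ks = [k for k in range(n) if k != i and k != j]
            # target i: match j vs alternative k ; target j: match i vs k
            p_i = expit(gram[i, j] - gram[i, ks])
            p_j = expit(gram[j, i] - gram[j, ks])
            s[i, j] = 0.5 * (p_i.mean() + p_j.mean())
    return SimilarityMatrix(items=list(emb.items), values=s, source="embedding")


def sim_from_rating_single(mean_ratings: np.ndarray, items: list, attribute: str) -> SimilarityMatrix:
    """Single-attribute rating similarity: S_ij = 100 - |r_i - r_j| for
    rater-averaged ratings on the 0-100 scale (diagonal exactly 100)."""
    r = np.asarray(mean_ratings, dtype=float)
    if r.ndim != 1 or len(r) != len(items):
        raise DataError("mean_ratings must be one value per item")
    if r.min() < 0 or r.max() > 100:
        raise DataError("ratings must lie on the 0-100 scale")
    values = 100.0 - np.abs(r[:, None] - r[None, :])
    return SimilarityMatrix(items=list(items), values=values, source=f"rating_single:{attribute}")


def sim_from_ratings_joint(single_matrices: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Joint rating similarity: entrywise root mean square of the
    per-attribute similarity matrices."""
    if not single_matrices:
        raise ParameterError("need at least one single-attribute matrix")
    items = single_matrices[0].items
    stack = []
    for m in single_matrices:
        if m.items != items:
            raise DataError("single-attribute matrices have mismatched items")
        stack.append(m.values)
    values = np.sqrt(np.mean(np.stack(stack) ** 2, axis=0))
    return SimilarityMatrix(items=list(items), values=values, source="rating_joint")


def matrix_correlation(
    a: SimilarityMatrix, b: SimilarityMatrix, include_diagonal: bool = False
) -> float:
    """Pearson correlation between two similarity matrices over the upper
    triangle (diagonal excluded unless flagged)."""
    if a.items != b.items:
        raise DataError("matrices must share item set and order")
    k = 0 if include_diagonal else 1
    iu = np.triu_indices(a.n, k=k)
    va, vb = a.values[iu], b.values[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DataError("correlation undefined for a constant matrix")
    return float(pearsonr(va, vb).statistic)
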