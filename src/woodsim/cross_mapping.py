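"""Regressions linking similarity dimensions, rating attributes,
similarity matrices, and image statistics.

All fits are ordinary least squares with an intercept (a no-intercept
toggle is provided as a sensitivity option).  Matrix targets are
vectorized over the upper triangle, optionally keeping the diagonal to
anchor scaling.  Fit quality is reported as the Pearson correlation r
between fitted and observed values (and r^2); no multiple-testing
correction is applied — the reported values are descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .errors import DataError, ParameterError
from .similarity import SimilarityMatrix
from .vice_embedding import Embedding


@dataclass
class RegressionResult:
    coefficients: np.ndarray
    intercept: float
    r: float
    r2: float
    predictor_labels: list[str]
    fitted: np.ndarray = field(repr=False, default=None)
    rank_deficient: bool = False

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.predictor_labels.index(label)])


def _ols(y: np.ndarray, X: np.ndarray, intercept: bool) -> tuple[np.ndarray, float, np.ndarray, bool]:
    n, p = X.shape
    design = np.column_stack([np.ones(n), X]) if intercept else X
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    deficient = rank < design.shape[1]
    fitted = design @ beta
    if intercept:
        return beta[1:], float(beta[0]), fitted, deficient
    return beta, 0.0, fitted, deficient


def _fit_r(y: np.ndarray, fitted: np.ndarray) -> float:
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(pearsonr(y, fitted).statistic)


def regress_vector(
    target: np.ndarray,
    predictors: np.ndarray,
    predictor_labels: list[str] | None = None,
    intercept: bool = True,
) -> RegressionResult:
    """OLS of one per-item target on per-item predictor columns.

    Warns when items barely outnumber predictors (over-fitting risk) and
    when the predictor matrix is rank deficient (a flagged minimum-norm
    solution is returned).
    """
    y = np.asarray(target, dtype=float)
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y):
        raise DataError("predictors and target have incompatible lengths")
    n, p = X.shape
    if n <= p + 1:
        warnings.warn(
            f"{n} observations for {p} predictors: fit is likely over-fitted", stacklevel=2
        )
    labels = predictor_labels or [f"x{j}" for j in range(p)]
    coefs, b0, fitted, deficient = _ols(y, X, intercept)
    if deficient:
        warnings.warn("rank-deficient predictors; minimum-norm solution returned", stacklevel=2)
    r = _fit_r(y, fitted)
    return RegressionResult(
        coefficients=coefs, intercept=b0, r=r, r2=r * r,
        predictor_labels=list(labels), fitted=fitted, rank_deficient=deficient,
    )


def _vectorize(m: SimilarityMatrix, keep_diagonal: bool) -> np.ndarray:
    iu = np.triu_indices(m.n, k=0 if keep_diagonal else 1)
    return m.values[iu]


def regress_matrix(
    target: SimilarityMatrix,
    predictors: list[SimilarityMatrix],
    keep_diagonal: bool = True,
    intercept: bool = True,
) -> tuple[RegressionResult, SimilarityMatrix]:
    """Multilinear regression of one similarity matrix on others.

    Upper triangles are vectorized (diagonal kept by default, anchoring
    the scale); returns the fit and the symmetric fitted matrix.
    """
    if not predictors:
        raise ParameterError("need at least one predictor matrix")
    for p in predictors:
        if p.items != target.items:
            raise DataError("predictor matrices must share the target's item order")
    y = _vectorize(target, keep_diagonal)
    X = np.column_stack([_vectorize(p, keep_diagonal) for p in predictors])
    labels = [p.source for p in predictors]
    result = regress_vector(y, X, predictor_labels=labels, intercept=intercept)

    n = target.n
    full = np.zeros((n, n))
    iu = np.triu_indices(n, k=0 if keep_diagonal else 1)
    full[iu] = result.fitted
    full = full + np.triu(full, k=1).T
    if not keep_diagonal:
        # diagonal not in the fit vector; fill from the model applied to it
        diag_X = np.column_stack([np.diag(p.values) for p in predictors])
        full[np.diag_indices(n)] = result.intercept + diag_X @ result.coefficients
    fitted_matrix = SimilarityMatrix(items=list(target.items), values=full, source="regression")
    return result, fitted_matrix


def leave_one_out_importance(
    target: SimilarityMatrix,
    predictors: list[SimilarityMatrix],
    keep_diagonal: bool = True,
    intercept: bool = True,
) -> dict[str, float]:
    """Per-predictor drop in fit correlation when that predictor is left
    out: drop_p = r_full - r_without_p.  Redundant predictors can show
    drops near zero or slightly negative.  A lone predictor's removal is
    reported as the full drop r_full."""
    full, _ = regress_matrix(target, predictors, keep_diagonal, intercept)
    drops: dict[str, float] = {}
    for i, p in enumerate(predictors):
        rest = predictors[:i] + predictors[i + 1 :]
        if not rest:
            drops[p.source] = full.r
            continue
        reduced, _ = regress_matrix(target, rest, keep_diagonal, intercept)
        drops[p.source] = full.r - reduced.r
    return drops


def attribute_correlation_and_pca(mean_ratings) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix between attribute mean-rating vectors,
    and the cumulative normalized eigenvalue spectrum of that correlation
    matrix (the rating space's effective dimensionality profile)."""
    X = np.asarray(mean_ratings, dtype=float)  # items x attributes
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("need an items x attributes matrix with >= 2 attributes")
    if (X.std(axis=0) == 0).any():
        raise DataError("constant attribute column; correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    cumvar = np.cumsum(eigvals) / eigvals.sum()
    return corr, cumvar


def reduced_dimension_regression(
    target: np.ndarray,
    emb: Embedding,
    k: int,
    intercept: bool = True,
) -> RegressionResult:
    """Refit a rating attribute on only the k most important similarity
    dimensions, ranked by absolute coefficient in the full fit."""
    if not 1 <= k <= emb.d:
        raise ParameterError(f"k must be in [1, {emb.d}]")
    labels = [f"dim_{j + 1}" for j in range(emb.d)]
    full = regress_vector(target, emb.loadings, predictor_labels=labels, intercept=intercept)
    top = np.argsort(-np.abs(full.coefficients), kind="stable")[:k]
    top = np.sort(top)
    return regress_vector(
        target, emb.loadings[:, top],
        predictor_labels=[labels[j] for j in top], intercept=intercept,
    )


def standardized_coefficients(result: RegressionResult, predictors: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Coefficients rescaled to SD units of predictors and target."""
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(target, dtype=float)
    return result.coefficients * X.std(axis=0) / y.std()
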