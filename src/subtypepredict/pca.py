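"""Supervised PCA of classifier-gene expression.

"Supervised" refers to the gene selection, not the decomposition: the PCA is
an ordinary covariance-based principal component analysis run on the subset
of genes that discriminate the subtypes at one hierarchy node.  Samples are
observations and classifier genes are variables, so component scores live in
sample space and distances between samples are computed on scores.

The decomposition is computed by SVD of the column-centered data matrix (no
scaling to unit variance, matching covariance-PCA semantics).  Equivalence
with a direct eigendecomposition of the sample covariance matrix is asserted
by tests, not assumed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateModelError, ParameterError
from .io import ExpressionMatrix

def _orient_signs(basis: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the arbitrary PCA sign: flip each component so its
    largest-magnitude gene loading is positive."""
    for k in range(basis.shape[1]):
        col = basis[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, k] = -col
            scores[:, k] = -scores[:, k]
    return basis, scores


class SupervisedPCA(TransformerMixin, BaseEstimator):
    """Covariance PCA with variance-proportion weights, sklearn style.

    Parameters
    ----------
    n_components : int or "all"
        Number of components to retain.  "all" keeps every component with
        nonzero variance, at most ``min(n_features, n_samples - 1)``.

    Attributes
    ----------
    components_ : ndarray (n_components, n_features)
        Orthonormal basis rows (gene loadings), sign-oriented so the
        largest-magnitude loading of each component is positive.
    mean_ : ndarray (n_features,)
        Per-gene centering vector.
    explained_variance_ : ndarray
        Component variances (divisor n - 1).
    weights_ : ndarray
        Per-component proportion of total variance; sums to 1 when all
        components are retained.
    scores_ : ndarray (n_samples, n_components)
        Component scores of the fitted samples.
    """

    def __init__(self, n_components: int | str = "all"):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ParameterError("X must be 2-d (samples x genes)")
        n, g = X.shape
        if n < 2:
            raise ParameterError(f"need at least 2 samples, got {n}")
        if g < 1:
            raise ParameterError("need at least 1 gene")
        max_k = min(g, n - 1)
        if self.n_components == "all":
            k = max_k
        else:
            k = int(self.n_components)
            if not 1 <= k <= max_k:
                raise ParameterError(
                    f"n_components={k} out of range [1, {max_k}] for {n} samples x {g} genes"
                )

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if s[0] <= 0 or not np.isfinite(s[0]):
            raise DegenerateModelError("zero-variance input: all samples are identical")
        total_var = float(np.sum(s**2))  # common factor (n-1) cancels in weights

        basis = Vt[:k].T.copy()
        scores = (U[:, :k] * s[:k]).copy()
        basis, scores = _orient_signs(basis, scores)

        self.n_components_ = k
        self.components_ = basis.T
        self.scores_ = scores
        self.singular_values_ = s[:k].copy()
        self.explained_variance_ = s[:k] ** 2 / (n - 1)
        self.weights_ = s[:k] ** 2 / total_var
        self.n_features_in_ = g
        self.n_samples_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self, "components_")
        return np.asarray(scores) @ self.components_ + self.mean_


@dataclass
class PCAProjection:
    """A fitted decomposition: basis (genes x components), per-sample scores,
    variance-proportion weight vector w, and the centering vector."""

    basis: np.ndarray
    scores: np.ndarray
    weights: np.ndarray
    center: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Samples x genes reconstruction; exact (to roundoff) when every
        component was retained."""
        return self.scores @ self.basis.T + self.center

    def score_row(self, sample_id: str) -> np.ndarray:
        return self.scores[self.sample_ids.index(sample_id)]


def fit_pca(matrix: ExpressionMatrix, n_components: int | str = "all") -> PCAProjection:
    """PCA of an expression matrix (genes x samples), treating samples as
    observations.  Scores are ordered by decreasing explained variance."""
    est = SupervisedPCA(n_components=n_components).fit(matrix.values.T)
    return PCAProjection(
        basis=est.components_.T,
        scores=est.scores_,
        weights=est.weights_,
        center=est.mean_,
        sample_ids=list(matrix.sample_ids),
        gene_ids=list(matrix.gene_ids),
    )


def merge_and_project(
    reference: ExpressionMatrix,
    unknown: pd.Series | np.ndarray,
    n_components: int | str = "all",
    unknown_id: str = "__unknown__",
) -> PCAProjection:
    """Merge one unknown profile into the reference and fit a single PCA on
    the combined matrix, as the published workflow prescribes.

    The unknown must cover every gene of the reference (align upstream per
    the missing-gene policy).  The unknown's scores are the last row.
    """
    if isinstance(unknown, pd.Series):
        missing = [g for g in reference.gene_ids if g not in unknown.index]
        if missing:
            raise ParameterError(
                f"unknown profile lacks reference genes {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        vec = unknown.reindex(reference.gene_ids).to_numpy(dtype=np.float64)
    else:
        vec = np.asarray(unknown, dtype=np.float64)
        if vec.shape != (reference.n_genes,):
            raise ParameterError(
                f"unknown vector has shape {vec.shape}, expected ({reference.n_genes},)"
            )
    if unknown_id in reference.sample_ids:
        raise ParameterError(f"unknown id {unknown_id!r} collides with a reference sample")
    merged = np.column_stack([reference.values, vec])
    matrix = ExpressionMatrix(
        list(reference.gene_ids), list(reference.sample_ids) + [unknown_id], merged
    )
    return fit_pca(matrix, n_components=n_components)
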