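"""Covariance PCA: oracle equivalence, invariants, merge-and-project."""

import numpy as np
import pandas as pd
import pytest

from subtypepredict import (
    DegenerateModelError,
    ExpressionMatrix,
    ParameterError,
    SupervisedPCA,
    fit_pca,
    merge_and_project,
)


def covariance_pca_oracle(X):
    """Brute-force reference: eigendecompose the sample covariance matrix of
    X (samples x genes) directly and project the centered data."""
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = min(X.shape[1], X.shape[0] - 1)
    basis = eigvec[:, :k]
    for j in range(k):  # same sign convention: largest-|loading| positive
        if basis[np.argmax(np.abs(basis[:, j])), j] < 0:
            basis[:, j] = -basis[:, j]
    scores = Xc @ basis
    weights = np.clip(eigval[:k], 0, None) / np.clip(eigval, 0, None).sum()
    return basis, scores, weights


def random_matrix(rng, n_genes, n_samples):
    return ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        rng.normal(size=(n_genes, n_samples)),
    )


class TestFitPCA:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        # 4 samples exactly on a line in 2-gene space
        t = np.array([0.0, 1.0, 2.0, 3.0])
        m = ExpressionMatrix(["g1", "g2"], [f"s{j}" for j in range(4)],
                             np.vstack([2 * t + 1, -t]))
        proj = fit_pca(m)
        np.testing.assert_allclose(proj.weights, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(proj.scores[:, 1], 0.0, atol=1e-9)

    def test_weights_sum_to_one_with_all_components(self):
        rng = np.random.default_rng(0)
        proj = fit_pca(random_matrix(rng, 6, 5))
        assert proj.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(proj.weights) <= 1e-12)  # sorted by variance

    def test_scores_match_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 6, 5)
        proj = fit_pca(m)
        basis, scores, weights = covariance_pca_oracle(m.values.T)
        np.testing.assert_allclose(proj.scores, scores, atol=1e-9)
        np.testing.assert_allclose(proj.basis, basis, atol=1e-9)
        np.testing.assert_allclose(proj.weights, weights, atol=1e-9)

    def test_basis_orthonormal_and_scores_uncorrelated(self):
        rng = np.random.default_rng(2)
        proj = fit_pca(random_matrix(rng, 8, 20))
        gram = proj.basis.T @ proj.basis
        np.testing.assert_allclose(gram, np.eye(proj.n_components), atol=1e-9)
        corr = np.corrcoef(proj.scores, rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 5, 12)
        proj = fit_pca(m)
        np.testing.assert_allclose(proj.reconstruct(), m.values.T, rtol=1e-8, atol=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 7, 9)
        a, b = fit_pca(m), fit_pca(m)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.basis, b.basis)

    def test_degenerate_and_parameter_errors(self):
        m = ExpressionMatrix(["g1", "g2"], ["s1", "s2", "s3"], np.ones((2, 3)))
        with pytest.raises(DegenerateModelError):
            fit_pca(m)
        rng = np.random.default_rng(5)
        with pytest.raises(ParameterError):
            fit_pca(random_matrix(rng, 4, 5), n_components=9)
        with pytest.raises(ParameterError):
            SupervisedPCA().fit(np.zeros((1, 3)))


class TestMergeAndProject:
    def test_duplicate_of_reference_sample_gets_identical_scores(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 10, 8)
        proj = merge_and_project(m, m.values[:, 2])
        np.testing.assert_allclose(proj.scores[-1], proj.scores[2], atol=1e-9)

    def test_row_count_grows_by_one(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 10, 8)
        proj = merge_and_project(m, rng.normal(size=10))
        assert proj.scores.shape[0] == 9
        assert proj.sample_ids[-1] == "__unknown__"

    def test_missing_gene_raises(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 4, 6)
        unknown = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(ParameterError, match="lacks reference genes"):
            merge_and_project(m, unknown)

    def test_unknown_from_separated_cluster_lands_with_its_cluster(self):
        # two well-separated clusters (per-gene shift 5, sigma 1, 20+20, 30 genes)
        rng = np.random.default_rng(9)
        mu = np.zeros((30, 1))
        a = rng.normal(size=(30, 20))
        b = 5.0 + rng.normal(size=(30, 20))
        m = ExpressionMatrix(
            [f"g{i}" for i in range(30)],
            [f"a{j}" for j in range(20)] + [f"b{j}" for j in range(20)],
            np.hstack([a, b]) + mu,
        )
        unknown = rng.normal(size=30)  # drawn from cluster a
        proj = merge_and_project(m, unknown)
        pc1_a = proj.scores[:20, 0]
        assert np.sign(proj.scores[-1, 0]) == np.sign(pc1_a.mean())
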