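import numpy as np
import pytest
from sklearn.linear_model import Lasso as SklearnLasso

from labnet import (
    LassoFit,
    ValidationError,
    estimate_lambda,
    lambda_max,
    lasso_fit,
    select_candidates,
)


def _standardized_column(rng, n):
    x = rng.normal(size=n)
    return (x - x.mean()) / x.std()


class TestEstimateLambda:
    def test_deterministic_given_seed(self, small_benchmark):
        _, matrix, _ = small_benchmark
        assert estimate_lambda(matrix, seed=42) == estimate_lambda(matrix, seed=42)

    def test_subset_size_is_ceil_of_fraction(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(30, 50))
        values = (values - values.mean(0)) / values.std(0)
        _, details = estimate_lambda(
            values, subset_fraction=0.10, seed=1, return_details=True
        )
        assert len(details["response_indices"]) == 5

    def test_lambda_within_grid_range(self, small_benchmark):
        _, matrix, _ = small_benchmark
        lam = estimate_lambda(matrix, seed=3)
        global_max = max(
            lambda_max(
                matrix.values[:, j], np.delete(matrix.values, j, axis=1)
            )
            for j in range(matrix.n_genes)
        )
        assert 1e-3 * global_max * 0.999 <= lam <= global_max * 1.001

    def test_too_few_samples_rejected(self):
        values = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(ValidationError):
            estimate_lambda(values, cv_folds=4)


class TestLassoFit:
    def test_single_covariate_soft_threshold(self):
        # one standardized covariate with x'y/n = 2.0 and lam = 0.5:
        # beta = S(2.0, 0.5) = 1.5
        n = 50
        rng = np.random.default_rng(1)
        x = _standardized_column(rng, n)
        z = rng.normal(size=n)
        z -= x * (x @ z) / (x @ x)  # orthogonal to x
        y = 2.0 * x + z
        assert abs(x @ y / n - 2.0) < 1e-12
        fit = lasso_fit(y, x[:, None], 0.5)
        assert fit.beta[0] == pytest.approx(1.5, abs=1e-6)

    def test_full_shrinkage_at_lambda_max(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] + 0.5 * rng.normal(size=40)
        y -= y.mean()
        lam_max = lambda_max(y, X)
        fit = lasso_fit(y, X, lam_max * 1.0001)
        assert np.all(fit.beta == 0.0)

    def test_ols_limit_small_lambda(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        X = (X - X.mean(0)) / X.std(0)
        beta_true = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ beta_true + 0.1 * rng.normal(size=60)
        y -= y.mean()
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        fit = lasso_fit(y, X, 1e-8)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_orthonormal_design_soft_threshold(self, seed):
        # columns orthogonal with norm sqrt(n) -> beta_j = S(x_j'y/n, lam)
        rng = np.random.default_rng(seed)
        n, p = 16, 4
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = q * np.sqrt(n)
        y = rng.normal(size=n)
        lam = 0.2
        correlations = X.T @ y / n
        expected = np.sign(correlations) * np.maximum(np.abs(correlations) - lam, 0)
        fit = lasso_fit(y, X, lam)
        np.testing.assert_allclose(fit.beta, expected, atol=1e-6)

    def test_monotone_sparsity_in_lambda(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 12))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, :4] @ np.array([2.0, -1.5, 1.0, 0.5]) + rng.normal(size=50)
        y -= y.mean()
        lam_max_value = lambda_max(y, X)
        nnz = [
            int(np.count_nonzero(lasso_fit(y, X, lam).beta))
            for lam in np.geomspace(1e-3 * lam_max_value, lam_max_value, 12)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_reference(self, seed):
        # independent cross-check of the coordinate-descent kernel
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 10))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] * 1.5 - X[:, 4] + 0.3 * rng.normal(size=30)
        y -= y.mean()
        for lam in (0.01, 0.1, 0.4):
            mine = lasso_fit(y, X, lam).beta
            reference = (
                SklearnLasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=10**6)
                .fit(X, y)
                .coef_
            )
            np.testing.assert_allclose(mine, reference, atol=1e-6)

    def test_rejects_bad_inputs(self):
        X = np.ones((5, 2))
        y = np.array([1.0, np.nan, 0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            lasso_fit(y, X, 0.1)
        with pytest.raises(ValidationError):
            lasso_fit(np.zeros(5), X, 0.0)


class TestSelectCandidates:
    def _fit(self, beta, predictor_indices=None):
        return LassoFit(
            response_index=99,
            beta=np.asarray(beta, dtype=float),
            lam=0.1,
            predictor_indices=predictor_indices,
        )

    def test_best_fraction_keeps_ceil(self):
        beta = np.linspace(1.0, 0.1, 10)
        candidates = select_candidates(self._fit(beta), best_fraction=0.8)
        assert len(candidates) == 8

    def test_all_zero_fit_gives_empty_set(self):
        candidates = select_candidates(self._fit(np.zeros(6)))
        assert len(candidates) == 0

    def test_sorted_by_absolute_coefficient(self):
        candidates = select_candidates(
            self._fit([0.9, -1.2, 0.3], predictor_indices=[0, 1, 2]),
            best_fraction=1.0,
        )
        assert list(candidates.indices) == [1, 0, 2]

    def test_response_never_among_predictors(self):
        with pytest.raises(ValidationError):
            LassoFit(
                response_index=1,
                beta=np.array([0.5, 0.2]),
                lam=0.1,
                predictor_indices=np.array([0, 1]),
            )
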