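"""Intercept-free Lasso regression of one gene on all others, and the
cross-validated estimation of the shared shrinkage factor.

The per-response objective is the standard coordinate-descent form

    (1 / 2n) * ||y - X beta||^2 + lambda * ||beta||_1

with no intercept (data are standardized globally beforehand). The shrinkage
factor lambda is estimated once, by 3-fold cross-validation on a random 10%
subset of response genes, and then reused for every response and every
permutation fit — re-selection stability, not per-gene tuning, is the
method's stabiliser.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from ._solver import solve_lasso
from .exceptions import ValidationError
from .types import ExpressionMatrix

__all__ = [
    "LassoFit",
    "CandidateSet",
    "estimate_lambda",
    "lasso_fit",
    "select_candidates",
    "lambda_max",
]

# Coefficient-update convergence tolerance for all Lasso solves.
TOLERANCE = 1e-7
MAX_ITER = 50_000


@dataclass
class LassoFit:
    """One intercept-free Lasso solution.

    ``beta[k]`` is the coefficient of predictor column ``k``;
    ``predictor_indices[k]`` maps it back to a gene index in the full matrix
    (the response gene itself is never a predictor).
    """

    response_index: int
    beta: np.ndarray
    lam: float
    predictor_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.predictor_indices is None:
            self.predictor_indices = np.arange(self.beta.size)
        self.predictor_indices = np.asarray(self.predictor_indices, dtype=int)
        if self.predictor_indices.size != self.beta.size:
            raise ValidationError("predictor_indices must align with beta")
        if self.response_index in self.predictor_indices:
            raise ValidationError("response gene appears among its predictors")

    @property
    def nonzero_indices(self) -> np.ndarray:
        """Gene indices with non-zero coefficients."""
        return self.predictor_indices[self.beta != 0]


@dataclass
class CandidateSet:
    """Step-1 candidates of one response: (gene index, |coefficient|) pairs
    sorted by |coefficient| decreasing (ties broken by gene index)."""

    response_index: int
    candidates: list[tuple[int, float]]

    @property
    def indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.candidates], dtype=int)

    @property
    def abs_coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.candidates], dtype=float)

    def __len__(self) -> int:
        return len(self.candidates)


def lambda_max(y: np.ndarray, X_others: np.ndarray) -> float:
    """Smallest lambda at which the Lasso solution is entirely zero:
    ``max_j |x_j' y| / n``."""
    n = y.shape[0]
    return float(np.abs(X_others.T @ y).max() / n)


def _as_values(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def estimate_lambda(
    X: ExpressionMatrix | np.ndarray,
    cv_folds: int = 3,
    subset_fraction: float = 0.10,
    grid_size: int = 100,
    seed: int | np.random.Generator = 0,
    return_details: bool = False,
) -> float | tuple[float, dict]:
    """Estimate the shared shrinkage factor by cross-validation.

    Draws ``ceil(subset_fraction * p)`` response genes without replacement,
    runs ``cv_folds``-fold CV for each over a log-spaced grid of
    ``grid_size`` lambda values from lambda_max down to 0.001 * lambda_max,
    records the lambda minimising mean held-out squared error, and returns
    the median of the recorded values. Deterministic given the seed.

    With ``return_details=True`` also returns a dict with the response
    indices used and their per-response optimal lambdas.
    """
    values = _as_values(X)
    n, p = values.shape
    if n < cv_folds:
        raise ValidationError(
            f"need at least cv_folds={cv_folds} samples, got {n}"
        )
    if not 0 < subset_fraction <= 1:
        raise ValidationError("subset_fraction must be in (0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_responses = max(1, math.ceil(subset_fraction * p))
    responses = np.sort(rng.choice(p, size=n_responses, replace=False))

    per_response: list[float] = []
    for j in responses:
        y = values[:, j]
        X_others = np.delete(values, j, axis=1)
        lam_max = lambda_max(y, X_others)
        if lam_max <= 0:  # response orthogonal to every predictor
            continue
        grid = np.geomspace(lam_max, 1e-3 * lam_max, grid_size)
        folds = KFold(
            n_splits=cv_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        mse = np.zeros(grid_size)
        for train, test in folds.split(values):
            with warnings.catch_warnings():
                # duality-gap convergence at the smallest grid lambdas is
                # immaterial for ranking lambdas by held-out MSE
                warnings.simplefilter("ignore", ConvergenceWarning)
                alphas, coefs, _ = lasso_path(
                    X_others[train], y[train], alphas=grid
                )
            predictions = X_others[test] @ coefs
            mse += ((y[test][:, None] - predictions) ** 2).mean(axis=0)
        # lasso_path returns alphas sorted decreasing, same as the grid
        per_response.append(float(alphas[int(np.argmin(mse))]))
    if not per_response:
        raise ValidationError("no usable response genes for lambda estimation")
    lam = float(np.median(per_response))
    if return_details:
        return lam, {"response_indices": responses, "lambdas": per_response}
    return lam


def lasso_fit(
    y: np.ndarray,
    X_others: np.ndarray,
    lam: float,
    response_index: int = -1,
    predictor_indices: np.ndarray | None = None,
    gram: np.ndarray | None = None,
) -> LassoFit:
    """Solve the intercept-free Lasso for one response.

    ``gram`` (``X_others' X_others / n``) may be precomputed and shared
    across repeated fits on the same predictor block (as in the permutation
    loop).
    """
    y = np.asarray(y, dtype=float)
    X_others = np.asarray(X_others, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X_others))):
        raise ValidationError("non-finite values in Lasso inputs")
    if lam <= 0:
        raise ValidationError(f"lambda must be > 0, got {lam}")
    beta = solve_lasso(
        y, X_others, lam, gram_n=gram, max_iter=MAX_ITER, tol=TOLERANCE
    )
    return LassoFit(
        response_index=response_index,
        beta=beta,
        lam=float(lam),
        predictor_indices=predictor_indices,
    )


def select_candidates(fit: LassoFit, best_fraction: float = 0.80) -> CandidateSet:
    """Keep the strongest fraction of non-zero step-1 coefficients.

    Non-zero coefficients are sorted by |coefficient| decreasing (ties by
    gene index ascending) and the first ``ceil(best_fraction * count)`` are
    retained as candidates for the permutation stage.
    """
    if not 0 < best_fraction <= 1:
        raise ValidationError("best_fraction must be in (0, 1]")
    nonzero = np.nonzero(fit.beta)[0]
    if nonzero.size == 0:
        return CandidateSet(response_index=fit.response_index, candidates=[])
    pairs = [
        (int(fit.predictor_indices[k]), float(abs(fit.beta[k]))) for k in nonzero
    ]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    keep = math.ceil(best_fraction * len(pairs))
    return CandidateSet(response_index=fit.response_index, candidates=pairs[:keep])
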