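"""scikit-learn-style estimator wrapping the full inference pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import PipelineConfig
from .evaluation import evaluate_networks
from .pipeline import run_pipeline
from .types import ExpressionMatrix, Network

__all__ = ["LassoStabilityNetwork"]


class LassoStabilityNetwork(BaseEstimator):
    """Gene-network inference by Lasso neighbourhood selection with
    permutation-based stability.

    Each gene is regressed on all others with an intercept-free Lasso at a
    single cross-validated shrinkage factor; a response-permutation counter
    procedure keeps the ``fanout`` most stable candidates per gene (gated by
    an empirical-null p-value); the directed selections are OR-symmetrised
    into a binary undirected network.

    Parameters
    ----------
    alpha : float or None
        Fixed shrinkage factor; ``None`` (default) estimates it by
        ``cv_folds``-fold cross-validation on ``lambda_subset_fraction`` of
        the genes.
    best_fraction : float
        Fraction of step-1 non-zero coefficients carried into the
        permutation stage (strongest first).
    fanout : int
        Maximum stable neighbours retained per response gene.
    permutations : int
        Number of response permutations B.
    significance_level, gate_enabled :
        Empirical-null gate on the smallest counter.
    symmetrise_rule : {"or", "and", "mean", "max", "min"}
        How the directed adjacency is symmetrised.
    standardize : bool
        Standardize columns (mean 0, sd 1) before fitting; the intercept-free
        Lasso assumes it.
    random_state : int
        Seed for every random choice; the result is independent of
        ``n_jobs``.
    n_jobs : int
        Gene-level parallelism.

    Attributes
    ----------
    alpha_ : float
        Shrinkage factor actually used.
    adjacency_ : ndarray of shape (p, p)
        Final symmetric binary adjacency.
    network_ : Network
        The same network with gene identifiers.
    directed_network_ : Network
        Pre-symmetrisation directed selections.
    results_ : list of StabilityResult
        Per-gene candidates, counters, selections and gate p-values.
    gene_ids_ : list of str

    Examples
    --------
    >>> from labnet import SimulationConfig, generate_gold_network, simulate_expression
    >>> cfg = SimulationConfig(p=10, n=50, seed=0)
    >>> gold = generate_gold_network(cfg)
    >>> X = simulate_expression(gold, cfg)
    >>> model = LassoStabilityNetwork(permutations=25, random_state=0).fit(X)
    >>> model.adjacency_.shape
    (10, 10)
    """

    def __init__(
        self,
        alpha: float | None = None,
        cv_folds: int = 3,
        lambda_subset_fraction: float = 0.10,
        grid_size: int = 100,
        best_fraction: float = 0.80,
        fanout: int = 1,
        permutations: int = 500,
        significance_level: float = 0.05,
        gate_enabled: bool = True,
        symmetrise_rule: str = "or",
        standardize: bool = True,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.alpha = alpha
        self.cv_folds = cv_folds
        self.lambda_subset_fraction = lambda_subset_fraction
        self.grid_size = grid_size
        self.best_fraction = best_fraction
        self.fanout = fanout
        self.permutations = permutations
        self.significance_level = significance_level
        self.gate_enabled = gate_enabled
        self.symmetrise_rule = symmetrise_rule
        self.standardize = standardize
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            cv_folds=self.cv_folds,
            lambda_subset_fraction=self.lambda_subset_fraction,
            grid_size=self.grid_size,
            best_fraction=self.best_fraction,
            fanout=self.fanout,
            permutations=self.permutations,
            significance_level=self.significance_level,
            gate_enabled=self.gate_enabled,
            symmetrise_rule=self.symmetrise_rule,
            seed=self.random_state,
            workers=self.n_jobs,
            lam=self.alpha,
        )

    def fit(self, X, y=None) -> "LassoStabilityNetwork":
        """Infer the network from an expression matrix.

        Parameters
        ----------
        X : ExpressionMatrix or array-like of shape (n_samples, n_genes)
            Arrays get synthetic gene ids ``G1..Gp``.
        y : ignored
        """
        if isinstance(X, ExpressionMatrix):
            matrix = X
        else:
            matrix = ExpressionMatrix(values=np.asarray(X, dtype=float))
        network, report = run_pipeline(
            matrix, self._config(), standardize_input=self.standardize
        )
        self.network_ = network
        self.adjacency_ = network.adjacency
        self.directed_network_ = report["directed_network"]
        self.results_ = report["results"]
        self.alpha_ = report["lambda"]
        self.gene_ids_ = list(network.gene_ids)
        self.n_features_in_ = len(self.gene_ids_)
        self.report_ = {
            k: v for k, v in report.items() if k not in ("results", "directed_network")
        }
        return self

    def score_network(self, gold: Network) -> dict[str, float]:
        """Compare the fitted network with a gold standard (confusion
        counts, rates, MCC, degree and betweenness correlations)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("fit the estimator before scoring")
        return evaluate_networks(self.network_, gold)
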