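"""End-to-end inference: standardize, estimate lambda once, infer every
gene's neighbourhood (in parallel across genes), assemble and symmetrise.

The whole run is a pure function of (expression matrix, config, seed): each
response gene draws its permutation stream from a substream keyed by its own
index, so the worker count never changes the result.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .assembly import assemble_adjacency, counter_matrix, symmetrise
from .config import PipelineConfig
from .io import read_expression_matrix, write_network
from .lasso import estimate_lambda
from .simulate import standardize
from .stability import StabilityResult, infer_neighbourhood
from .types import ExpressionMatrix, Network

__all__ = ["run_pipeline", "run_permutation_sweep"]

logger = logging.getLogger(__name__)


def run_pipeline(
    expression: str | Path | ExpressionMatrix,
    config: PipelineConfig,
    output_path: str | Path | None = None,
    counters_path: str | Path | None = None,
    orientation: str = "genes-in-rows",
    standardize_input: bool = True,
) -> tuple[Network, dict]:
    """Infer an undirected gene network from an expression matrix.

    Returns the symmetrised network and a run report (shrinkage factor,
    per-gene selection sizes, edge counts). Optionally writes the edge list
    and the diagnostic counter matrix.
    """
    if isinstance(expression, (str, Path)):
        matrix = read_expression_matrix(expression, orientation=orientation)
    else:
        matrix = expression
    standardized = standardize(matrix) if standardize_input else matrix
    p = standardized.n_genes

    if config.lam is not None:
        lam = float(config.lam)
        logger.info("using fixed shrinkage factor lambda=%.6g", lam)
    else:
        lam = estimate_lambda(
            standardized,
            cv_folds=config.cv_folds,
            subset_fraction=config.lambda_subset_fraction,
            grid_size=config.grid_size,
            seed=np.random.default_rng([config.seed, 1]),
        )
        logger.info("estimated shrinkage factor lambda=%.6g", lam)

    results: list[StabilityResult] = Parallel(n_jobs=config.workers)(
        delayed(infer_neighbourhood)(
            j, standardized.values, lam, config, config.seed
        )
        for j in range(p)
    )
    for result in results:
        if not result.selected:
            logger.info(
                "gene %s: empty selection (p-value %s)",
                standardized.gene_ids[result.response_index],
                result.p_value,
            )

    directed = assemble_adjacency(results, gene_ids=standardized.gene_ids)
    network = symmetrise(directed, rule=config.symmetrise_rule)

    report = {
        "lambda": lam,
        "n_genes": p,
        "n_samples": standardized.n_samples,
        "selection_sizes": {
            standardized.gene_ids[r.response_index]: len(r.selected)
            for r in results
        },
        "n_edges_directed": directed.n_edges,
        "n_edges": network.n_edges,
        # rich objects for programmatic callers (not serialised by the CLI)
        "results": results,
        "directed_network": directed,
    }

    if output_path is not None:
        write_network(network, output_path)
    if counters_path is not None:
        counters = counter_matrix(results, p)
        np.savetxt(
            counters_path,
            counters,
            fmt="%d",
            delimiter="\t",
            header="\t".join(standardized.gene_ids),
            comments="",
        )
    return network, report


def _sweep_one_gene(
    j: int,
    values: np.ndarray,
    lam: float,
    config: PipelineConfig,
    b_grid: list[int],
):
    """Step 1 once, then counters checkpointed at every B of the grid."""
    from .lasso import lasso_fit, select_candidates
    from .stability import permutation_counters, select_stable

    y = values[:, j]
    predictor_indices = np.delete(np.arange(values.shape[1]), j)
    X_others = values[:, predictor_indices]
    fit = lasso_fit(
        y, X_others, lam, response_index=j, predictor_indices=predictor_indices
    )
    candidates = select_candidates(fit, best_fraction=config.best_fraction)
    rng = np.random.default_rng([config.seed, 0, j])
    snapshots = permutation_counters(
        y,
        X_others,
        lam,
        candidates,
        B=max(b_grid),
        seed=rng,
        predictor_indices=predictor_indices,
        checkpoints=sorted(b_grid),
    )
    results = []
    for row, B in zip(snapshots, sorted(b_grid)):
        results.append(
            select_stable(
                row,
                candidates,
                fanout=config.fanout,
                B=B,
                significance_level=config.significance_level,
                gate_enabled=config.gate_enabled,
            )
        )
    return results


def run_permutation_sweep(
    expression: str | Path | ExpressionMatrix,
    config: PipelineConfig,
    b_grid: list[int],
) -> dict[int, tuple[Network, dict]]:
    """Run the pipeline for several permutation counts B at once.

    Because each response gene consumes one sequential permutation stream,
    the counters after the first B permutations are identical to an
    independent run with that B; step-1 fits and the shrinkage factor are
    B-independent and shared. The result maps each B of ``b_grid`` to the
    same ``(network, report)`` pair ``run_pipeline`` would produce.
    """
    if not b_grid or any(b < 0 for b in b_grid):
        raise ValueError("b_grid must be non-empty with non-negative entries")
    if isinstance(expression, (str, Path)):
        matrix = read_expression_matrix(expression)
    else:
        matrix = expression
    standardized = standardize(matrix)
    p = standardized.n_genes
    if config.lam is not None:
        lam = float(config.lam)
    else:
        lam = estimate_lambda(
            standardized,
            cv_folds=config.cv_folds,
            subset_fraction=config.lambda_subset_fraction,
            grid_size=config.grid_size,
            seed=np.random.default_rng([config.seed, 1]),
        )
    ordered = sorted(set(b_grid))
    per_gene = Parallel(n_jobs=config.workers)(
        delayed(_sweep_one_gene)(j, standardized.values, lam, config, ordered)
        for j in range(p)
    )
    output: dict[int, tuple[Network, dict]] = {}
    for k, B in enumerate(ordered):
        results = [per_gene[j][k] for j in range(p)]
        directed = assemble_adjacency(results, gene_ids=standardized.gene_ids)
        network = symmetrise(directed, rule=config.symmetrise_rule)
        report = {
            "lambda": lam,
            "n_genes": p,
            "n_samples": standardized.n_samples,
            "n_edges_directed": directed.n_edges,
            "n_edges": network.n_edges,
            "results": results,
            "directed_network": directed,
        }
        output[B] = (network, report)
    return output
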