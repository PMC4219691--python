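"""Synthetic benchmark generator: scale-free gold networks and matching
expression data.

The generator emulates, at desk scale, the statistical structure of in-silico
microarray benchmarks: a scale-free gold-standard topology (preferential
attachment) and per-gene expression values that are noisy linear functions of
network neighbours. Mechanistic ODE/SDE kinetics are deliberately replaced by
a linear structural equation model — the inference method assumes local
linearity, so a linear generator is the matching null ecosystem. An optional
block of near-duplicate genes injects the multicollinearity that motivates
the permutation-stability step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .types import ExpressionMatrix, Network

__all__ = [
    "SimulationConfig",
    "generate_gold_network",
    "simulate_expression",
    "standardize",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    Attributes
    ----------
    p, n : int
        Gene and sample counts (defaults 50 genes, 100 samples).
    attachment_edges : int
        Edges added per new node in preferential attachment; 1 gives a tree.
    coef_low, coef_high : float
        Bounds on |edge coefficient| of the linear model; signs are random.
    noise_sd : float
        Standard deviation of the additive Gaussian noise on non-root genes.
    collinear_block_size : int
        Number of extra near-duplicate genes appended to the matrix.
    collinear_rho : float
        Target correlation between a duplicate and its source gene.
    seed : int
        Seed for every random choice (topology, orientation, coefficients,
        noise, duplicates).
    """

    p: int = 50
    n: int = 100
    attachment_edges: int = 1
    coef_low: float = 0.5
    coef_high: float = 1.5
    noise_sd: float = 0.1
    collinear_block_size: int = 0
    collinear_rho: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValidationError(f"p must be >= 2, got {self.p}")
        if self.n < 3:
            raise ValidationError(f"n must be >= 3, got {self.n}")
        if self.attachment_edges < 1:
            raise ValidationError("attachment_edges must be >= 1")
        if not 0 < self.coef_low <= self.coef_high:
            raise ValidationError(
                "need 0 < coef_low <= coef_high, got "
                f"[{self.coef_low}, {self.coef_high}]"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.collinear_block_size < 0:
            raise ValidationError("collinear_block_size must be >= 0")
        if not 0 <= self.collinear_rho < 1:
            raise ValidationError("collinear_rho must be in [0, 1)")


def generate_gold_network(config: SimulationConfig) -> Network:
    """Generate an undirected connected scale-free network on ``p`` genes.

    Barabasi-Albert preferential attachment with ``attachment_edges`` edges
    per new node; deterministic given ``config.seed``.
    """
    if config.attachment_edges >= config.p:
        raise ValidationError(
            f"attachment_edges ({config.attachment_edges}) must be < p ({config.p})"
        )
    graph = nx.barabasi_albert_graph(
        config.p, config.attachment_edges, seed=config.seed
    )
    adjacency = nx.to_numpy_array(graph, nodelist=range(config.p), dtype=int)
    gene_ids = [f"G{j + 1}" for j in range(config.p)]
    return Network(gene_ids=gene_ids, adjacency=adjacency, directed=False)


def simulate_expression(
    network: Network,
    config: SimulationConfig,
    return_model: bool = False,
) -> ExpressionMatrix | tuple[ExpressionMatrix, dict]:
    """Simulate steady-state expression from a gold network.

    A random acyclic orientation of the (undirected) network is fixed by the
    seed: genes are put in a random order and every edge points from the
    earlier to the later gene. Root genes are standard normal; every other
    gene is the signed-coefficient sum of its parents plus
    ``N(0, noise_sd**2)`` noise. Coefficient magnitudes are uniform in
    ``[coef_low, coef_high]`` with random sign. Optionally appends
    ``collinear_block_size`` genes that are ``collinear_rho``-correlated
    copies of randomly chosen existing genes.

    With ``return_model=True`` also returns a dict with the topological
    ``order``, per-gene ``parents`` and edge ``coefficients`` used, which is
    convenient for parameter-recovery checks.
    """
    p = network.n_genes
    rng = np.random.default_rng([config.seed, 1])
    order = rng.permutation(p)
    position = np.empty(p, dtype=int)
    position[order] = np.arange(p)

    adjacency = network.adjacency != 0
    if network.directed:
        adjacency = adjacency | adjacency.T
    parents: dict[int, list[int]] = {}
    coefficients: dict[tuple[int, int], float] = {}
    for g in range(p):
        pars = [
            h for h in np.nonzero(adjacency[g])[0] if position[h] < position[g]
        ]
        parents[g] = pars
        for h in pars:
            magnitude = rng.uniform(config.coef_low, config.coef_high)
            sign = rng.choice([-1.0, 1.0])
            coefficients[(h, g)] = sign * magnitude

    values = np.zeros((config.n, p))
    for g in order:
        pars = parents[g]
        if not pars:
            values[:, g] = rng.standard_normal(config.n)
        else:
            values[:, g] = sum(
                coefficients[(h, g)] * values[:, h] for h in pars
            ) + config.noise_sd * rng.standard_normal(config.n)

    gene_ids = list(network.gene_ids)
    if config.collinear_block_size > 0:
        clones = np.zeros((config.n, config.collinear_block_size))
        rho = config.collinear_rho
        for k in range(config.collinear_block_size):
            src = int(rng.integers(p))
            x = values[:, src]
            clones[:, k] = rho * x + math.sqrt(1 - rho**2) * x.std() * (
                rng.standard_normal(config.n)
            )
            gene_ids.append(f"{network.gene_ids[src]}_clone{k + 1}")
        values = np.hstack([values, clones])

    matrix = ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=[f"S{i + 1}" for i in range(config.n)],
    )
    if return_model:
        model = {
            "order": order,
            "parents": parents,
            "coefficients": coefficients,
        }
        return matrix, model
    return matrix


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene column to mean 0 and standard deviation 1.

    The standard deviation uses denominator ``n`` (population form). The
    intercept-free Lasso assumes centred, unit-scale columns, so the whole
    matrix is standardized once before any fit.

    Raises
    ------
    ValidationError
        If a gene has zero variance (named in the message).
    """
    values = matrix.values
    sd = values.std(axis=0, ddof=0)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValidationError(
            f"gene {matrix.gene_ids[int(zero[0])]!r} has zero variance"
        )
    centred = (values - values.mean(axis=0)) / sd
    return ExpressionMatrix(
        values=centred,
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
    )
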