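"""Assembling the directed adjacency matrix from per-gene selections and
symmetrising it into the final undirected network."""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .stability import StabilityResult
from .types import Network

__all__ = ["assemble_adjacency", "symmetrise", "symmetrise_matrix", "counter_matrix"]


def assemble_adjacency(
    results: list[StabilityResult],
    p: int | None = None,
    gene_ids: list[str] | None = None,
) -> Network:
    """Build the directed binary adjacency from stability selections.

    ``A[i, j] = 1`` iff gene ``j`` is in the selected neighbour set of
    response ``i``. Either ``p`` or ``gene_ids`` must be given.
    """
    if gene_ids is None:
        if p is None:
            raise ValidationError("either p or gene_ids is required")
        gene_ids = [f"G{j + 1}" for j in range(p)]
    p = len(gene_ids)
    seen: set[int] = set()
    adjacency = np.zeros((p, p), dtype=int)
    for result in results:
        i = result.response_index
        if i in seen:
            raise ValidationError(f"duplicate StabilityResult for response {i}")
        seen.add(i)
        if not 0 <= i < p:
            raise ValidationError(f"response index {i} out of range for p={p}")
        for j in result.selected:
            if i == j:
                raise ValidationError("self-selection is not permitted")
            adjacency[i, j] = 1
    return Network(gene_ids=gene_ids, adjacency=adjacency, directed=True)


def counter_matrix(results: list[StabilityResult], p: int) -> np.ndarray:
    """Diagnostic p x p matrix of permutation counters: entry (i, j) is the
    counter of candidate j for response i (0 for non-candidates)."""
    matrix = np.zeros((p, p), dtype=int)
    for result in results:
        matrix[result.response_index, result.candidate_indices] = result.counters
    return matrix


def symmetrise_matrix(adjacency: np.ndarray, rule: str = "or") -> np.ndarray:
    """Symmetrise a (possibly weighted) adjacency and binarise it.

    ``or``/``and`` operate on presence/absence; ``mean``/``max``/``min``
    combine the two directed weights and then binarise at > 0.
    """
    a = np.asarray(adjacency, dtype=float)
    if rule == "or":
        combined = np.maximum(a != 0, a.T != 0)
    elif rule == "and":
        combined = np.minimum(a != 0, a.T != 0)
    elif rule == "mean":
        combined = (a + a.T) / 2 > 0
    elif rule == "max":
        combined = np.maximum(a, a.T) > 0
    elif rule == "min":
        combined = np.minimum(a, a.T) > 0
    else:
        raise ValidationError(f"unknown symmetrisation rule {rule!r}")
    result = combined.astype(int)
    np.fill_diagonal(result, 0)
    return result


def symmetrise(network: Network, rule: str = "or") -> Network:
    """Symmetrise a directed network into an undirected one.

    The OR rule (the pipeline default) declares genes associated if at least
    one of the two directed selections is present; AND requires both.
    """
    return Network(
        gene_ids=list(network.gene_ids),
        adjacency=symmetrise_matrix(network.adjacency, rule=rule),
        directed=False,
    )
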