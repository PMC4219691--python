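"""Core in-memory containers: expression matrices and binary gene networks.

Conventions used throughout the package:

* expression matrices are stored samples x genes (``n x p``);
* networks are binary adjacency matrices over an ordered gene list, with a
  zero diagonal (self-interactions are excluded by design); an undirected
  network has a symmetric adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["ExpressionMatrix", "Network"]


@dataclass
class ExpressionMatrix:
    """Expression values for ``n`` samples by ``p`` genes.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Finite real expression values in arbitrary units.
    gene_ids : sequence of str
        Unique gene identifiers, one per column.
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"G{j + 1}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != p:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {p} gene columns"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} sample rows"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id {dup!r}")
        if p < 2:
            raise ValidationError(f"need at least 2 genes, got {p}")
        if n < 3:
            raise ValidationError(f"need at least 3 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Network:
    """A gene network as a binary adjacency matrix.

    ``adjacency[i, j] == 1`` means gene ``j`` is linked to gene ``i`` (for a
    directed network, gene ``j`` was selected as a neighbour of response
    ``i``). Undirected networks must be symmetric; the diagonal is always
    zero.
    """

    gene_ids: list[str]
    adjacency: np.ndarray
    directed: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.adjacency = np.asarray(self.adjacency)
        p = len(self.gene_ids)
        if self.adjacency.shape != (p, p):
            raise ValidationError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{p} gene ids"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id {dup!r}")
        if np.any(np.diagonal(self.adjacency) != 0):
            raise ValidationError("adjacency has non-zero diagonal entries")
        if not self.directed and not np.array_equal(
            self.adjacency, self.adjacency.T
        ):
            raise ValidationError("undirected network has asymmetric adjacency")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        """Number of edges: arcs if directed, unordered pairs otherwise."""
        nnz = int(np.count_nonzero(self.adjacency))
        return nnz if self.directed else nnz // 2

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as id pairs; unordered pairs are lexicographically sorted."""
        edges: set[tuple[str, str]] = set()
        rows, cols = np.nonzero(self.adjacency)
        for i, j in zip(rows.tolist(), cols.tolist()):
            a, b = self.gene_ids[i], self.gene_ids[j]
            if self.directed:
                edges.add((a, b))
            else:
                edges.add((a, b) if a <= b else (b, a))
        return edges

    def degree(self) -> np.ndarray:
        """Per-gene degree (undirected) or total degree (in+out, directed)."""
        a = (self.adjacency != 0).astype(int)
        if self.directed:
            return a.sum(axis=0) + a.sum(axis=1)
        return a.sum(axis=1)


def _first_duplicate(ids: list[str]) -> str | None:
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            return g
        seen.add(g)
    return None
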