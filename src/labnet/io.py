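"""Reading and writing expression matrices and edge-list networks.

Expression files are delimited text with one header row of sample ids and a
first column of gene ids (genes-in-rows, the default) or the transpose.
Networks travel as 2- or 3-column edge lists (source, target, optional
weight), the format used by GeneNetWeaver-style gold standards, where a
third column equal to 0 marks a known-absent edge.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .types import ExpressionMatrix, Network

__all__ = ["read_expression_matrix", "read_gold_network", "write_network"]

logger = logging.getLogger(__name__)

_ORIENTATIONS = ("genes-in-rows", "genes-in-columns")


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix from delimited text.

    Parameters
    ----------
    path : path
        TSV or CSV file; the delimiter is inferred from the extension
        (``.csv`` -> comma, anything else -> tab) unless ``delimiter`` is
        given.
    orientation : {"genes-in-rows", "genes-in-columns"}
        Layout of the file. The returned matrix is always samples x genes.

    Raises
    ------
    FormatError
        If a cell is missing or non-numeric (the error names its location).
    ValidationError
        On duplicate gene ids or fewer than 3 samples.
    """
    path = Path(path)
    if orientation not in _ORIENTATIONS:
        raise ValidationError(
            f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
        )
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(df.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"non-numeric or missing value in {path.name} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "genes-in-rows":
        gene_ids, sample_ids = list(df.index), list(df.columns)
        values = df.to_numpy(dtype=float).T
    else:
        gene_ids, sample_ids = list(df.columns), list(df.index)
        values = df.to_numpy(dtype=float)
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    orientation: str = "genes-in-rows",
    delimiter: str | None = None,
) -> None:
    """Write an expression matrix as delimited text (inverse of the reader)."""
    path = Path(path)
    if orientation not in _ORIENTATIONS:
        raise ValidationError(
            f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
        )
    sep = _infer_delimiter(path, delimiter)
    df = pd.DataFrame(
        matrix.values.T, index=matrix.gene_ids, columns=matrix.sample_ids
    )
    if orientation == "genes-in-columns":
        df = df.T
    df.to_csv(path, sep=sep)


def read_gold_network(path: str | Path, gene_ids: list[str]) -> Network:
    """Load a gold-standard edge list as a directed binary network.

    Rows are ``source<TAB>target[<TAB>weight]`` (any whitespace accepted).
    A third column equal to 0 is an explicit negative and adds no edge;
    non-zero or missing third columns add the edge. Self-edges are skipped
    with a warning; edges naming unknown genes raise ``ValidationError``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, engine="python", dtype=str
        )
    except pd.errors.EmptyDataError:
        p = len(gene_ids)
        return Network(gene_ids=list(gene_ids), adjacency=np.zeros((p, p), dtype=int), directed=True)
    if df.shape[1] not in (2, 3):
        raise FormatError(
            f"{path.name}: expected 2 or 3 columns, found {df.shape[1]}"
        )
    index = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    adjacency = np.zeros((p, p), dtype=int)
    for row in df.itertuples(index=False):
        source, target = str(row[0]), str(row[1])
        for g in (source, target):
            if g not in index:
                raise ValidationError(
                    f"{path.name}: edge references unknown gene id {g!r}"
                )
        if source == target:
            logger.warning(
                "%s: skipping self-edge on %r (self-interactions excluded)",
                path.name,
                source,
            )
            continue
        if df.shape[1] == 3:
            try:
                weight = float(row[2])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path.name}: non-numeric weight {row[2]!r} on edge "
                    f"{source}->{target}"
                ) from exc
            if weight == 0:
                continue
        adjacency[index[source], index[target]] = 1
    return Network(gene_ids=list(gene_ids), adjacency=adjacency, directed=True)


def write_network(network: Network, path: str | Path, header: bool = False) -> None:
    """Write a network as a 3-column TSV edge list.

    Directed networks emit one row per arc. Undirected networks emit each
    unordered pair once, with the lexicographically smaller id as source.
    Rows are sorted for byte-level reproducibility.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    r, c = np.nonzero(network.adjacency)
    for i, j in zip(r.tolist(), c.tolist()):
        a, b = network.gene_ids[i], network.gene_ids[j]
        if network.directed:
            rows.append((a, b))
        elif i < j:
            rows.append((a, b) if a <= b else (b, a))
    rows.sort()
    with open(path, "w") as fh:
        if header:
            fh.write("source\ttarget\tweight\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\t1\n")


def restrict_network(network: Network, gene_ids: list[str]) -> Network:
    """Induced subnetwork on ``gene_ids`` (all must exist), in that order."""
    index = {g: i for i, g in enumerate(network.gene_ids)}
    missing = [g for g in gene_ids if g not in index]
    if missing:
        raise ValidationError(f"unknown gene ids: {missing[:5]}")
    sel = np.array([index[g] for g in gene_ids])
    return Network(
        gene_ids=list(gene_ids),
        adjacency=network.adjacency[np.ix_(sel, sel)],
        directed=network.directed,
    )
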