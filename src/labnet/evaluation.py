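"""Scoring a predicted network against a gold standard.

All comparisons are over unordered gene pairs of an undirected prediction:
confusion counts, TPR/FPR/precision, the Matthews correlation coefficient,
and topology conservation via Pearson correlation of per-gene degree and
(unnormalised) betweenness-centrality vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .assembly import symmetrise
from .exceptions import ValidationError
from .types import Network

__all__ = [
    "ConfusionTable",
    "confusion_counts",
    "mcc",
    "rates",
    "degree_vector",
    "betweenness_vector",
    "centrality_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionTable:
    """Edge-prediction confusion counts over unordered gene pairs."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _as_undirected(network: Network) -> Network:
    return symmetrise(network, rule="or") if network.directed else network


def confusion_counts(predicted: Network, gold: Network) -> ConfusionTable:
    """Count TP/FP/FN/TN over all unordered gene pairs.

    Both networks must share the same ordered gene list; a directed gold
    standard is OR-symmetrised before comparison.
    """
    if predicted.gene_ids != gold.gene_ids:
        raise ValidationError("predicted and gold networks have different genes")
    pred = _as_undirected(predicted).adjacency != 0
    true = _as_undirected(gold).adjacency != 0
    iu = np.triu_indices(len(predicted.gene_ids), k=1)
    p_edges, t_edges = pred[iu], true[iu]
    return ConfusionTable(
        TP=int(np.sum(p_edges & t_edges)),
        FP=int(np.sum(p_edges & ~t_edges)),
        FN=int(np.sum(~p_edges & t_edges)),
        TN=int(np.sum(~p_edges & ~t_edges)),
    )


def mcc(ct: ConfusionTable) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; if any factor
    of the denominator is zero the coefficient is 0 by convention (so an
    empty prediction scores 0, not the inflated value a TN-dominated
    accuracy would give on a sparse network).
    """
    tp, fp, fn, tn = (float(x) for x in (ct.TP, ct.FP, ct.FN, ct.TN))
    denominator = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denominator == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denominator)


def rates(ct: ConfusionTable) -> dict[str, float]:
    """True-positive rate, false-positive rate and precision (0/0 -> 0)."""

    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    return {
        "tpr": _ratio(ct.TP, ct.TP + ct.FN),
        "fpr": _ratio(ct.FP, ct.FP + ct.TN),
        "precision": _ratio(ct.TP, ct.TP + ct.FP),
    }


def degree_vector(network: Network) -> np.ndarray:
    """Per-gene degree of an undirected network."""
    return _as_undirected(network).degree().astype(float)


def betweenness_vector(network: Network) -> np.ndarray:
    """Unnormalised betweenness centrality per gene.

    For gene v, the sum over unordered pairs (s, t), s != v != t, of the
    fraction of shortest s-t paths that pass through v; disconnected pairs
    contribute 0.
    """
    undirected = _as_undirected(network)
    graph = nx.from_numpy_array(undirected.adjacency)
    centrality = nx.betweenness_centrality(graph, normalized=False)
    return np.array([centrality[v] for v in range(undirected.n_genes)])


def centrality_correlation(
    a: np.ndarray, b: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation between two per-gene centrality vectors.

    Pearson by default; Spearman available via ``method="spearman"``. If
    either vector is constant the correlation is undefined and NaN is
    returned with a logged warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"centrality vectors differ in length: {a.shape} vs {b.shape}"
        )
    if a.size < 3:
        raise ValidationError("need at least 3 genes for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("centrality correlation undefined: constant vector")
        return float("nan")
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def evaluate_networks(predicted: Network, gold: Network) -> dict[str, float]:
    """Full comparison report: confusion counts, rates, MCC and the two
    topology-conservation correlations."""
    ct = confusion_counts(predicted, gold)
    report: dict[str, float] = {
        "TP": ct.TP,
        "FP": ct.FP,
        "FN": ct.FN,
        "TN": ct.TN,
        **rates(ct),
        "mcc": mcc(ct),
        "degree_correlation": centrality_correlation(
            degree_vector(predicted), degree_vector(gold)
        ),
        "betweenness_correlation": centrality_correlation(
            betweenness_vector(predicted), betweenness_vector(gold)
        ),
    }
    return report
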