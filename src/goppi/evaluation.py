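"""Evaluation of protein rankings against a gold-standard essential set.

Covers the quantities used to compare original and refined networks:
top-k true-positive counts and precision (TP / (TP + FP)), the
essential-protein portion of a network, edge classes among the top-k
induced subgraph (both endpoints essential / mixed / neither), rank-based
ROC curves with trapezoidal AUC, percentage improvement between two
counts, and threshold sweeps.

Every network variant is evaluated against the gold standard restricted
to its own node set: proteins absent from a network can be neither true
nor false positives there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import centrality
from .network import EdgeScoreTable, PpiNetwork, refine

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Unusable evaluation input (empty gold standard, single class...)."""


@dataclass(frozen=True)
class GoldStandard:
    """Set of known essential proteins (the positive class)."""

    essential: frozenset[str]

    def __post_init__(self):
        if not self.essential:
            raise EvaluationError("gold standard is empty")

    def restricted_to(self, universe) -> frozenset[str]:
        return self.essential & frozenset(universe)

    @classmethod
    def from_file(cls, path) -> "GoldStandard":
        with open(path, encoding="utf-8") as fh:
            ids = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
        return cls(essential=frozenset(ids))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for p in sorted(self.essential):
                fh.write(p + "\n")


def count_true_top_k(ranking: list[str], gold: GoldStandard, k: int) -> int:
    """Number of essential proteins among the top-k ranked."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ess = gold.restricted_to(ranking)
    if not ess:
        raise EvaluationError("no gold-standard protein appears in the ranking")
    return len(set(ranking[:k]) & ess)


def precision_top_k(ranking: list[str], gold: GoldStandard, k: int) -> float:
    """TP / (TP + FP) over the top min(k, |P|) predictions."""
    tp = count_true_top_k(ranking, gold, k)
    return tp / min(k, len(ranking))


def essential_portion(net: PpiNetwork, gold: GoldStandard) -> float:
    """Fraction of network proteins that are essential."""
    if net.n_nodes == 0:
        raise EvaluationError("network has no proteins")
    return len(gold.restricted_to(net.nodes)) / net.n_nodes


def essential_portion_from_counts(n_proteins: int, n_essential: int) -> float:
    """Essential portion from published node/essential counts alone."""
    if n_proteins <= 0:
        raise ValueError("need a positive protein count")
    if not 0 <= n_essential <= n_proteins:
        raise ValueError("essential count must lie in [0, n_proteins]")
    return n_essential / n_proteins


def edge_class_portions(
    net: PpiNetwork, ranking: list[str], gold: GoldStandard, k: int
) -> dict[str, float]:
    """Edge-class fractions over the subgraph induced by the top-k proteins.

    Classes: ess_ess (both endpoints essential), ess_noness (mixed),
    noness_noness.  An edgeless induced subgraph yields all-zero portions
    with a warning.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    top = set(ranking[:k])
    ess = gold.restricted_to(net.nodes)
    sub = net.subgraph_of(top)
    counts = {"ess_ess": 0, "ess_noness": 0, "noness_noness": 0}
    for a, b in sub.edges:
        n_ess = (a in ess) + (b in ess)
        key = ("noness_noness", "ess_noness", "ess_ess")[n_ess]
        counts[key] += 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("induced top-%d subgraph has no edges; portions are all zero", k)
        return {cls: 0.0 for cls in counts}
    return {cls: c / total for cls, c in counts.items()}


def rank_scores(ranking: list[str]) -> dict[str, float]:
    """Normalised rank score 1 - (rank-1)/|P|, so rank 1 maps to 1.0."""
    n = len(ranking)
    return {p: 1.0 - i / n for i, p in enumerate(ranking)}


def roc_auc(ranking: list[str], gold: GoldStandard) -> tuple[np.ndarray, float]:
    """ROC staircase and trapezoidal AUC from a ranking.

    Each protein's normalised rank score is thresholded over [0, 1]; the
    resulting (fpr, tpr) staircase runs from (0, 0) to (1, 1).  On
    tie-free rankings the AUC equals the concordant-pair (Mann-Whitney)
    statistic.
    """
    universe = set(ranking)
    ess = gold.restricted_to(universe)
    if not ess or ess == universe:
        raise EvaluationError("ROC needs both an essential and a nonessential class")
    scores = rank_scores(ranking)
    y = np.array([p in ess for p in ranking], dtype=int)
    s = np.array([scores[p] for p in ranking])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def improvement(count_refined: float, count_original: float) -> float:
    """Percentage improvement 100 (refined - original) / original."""
    if count_original <= 0:
        raise ValueError("baseline count must be positive")
    return 100.0 * (count_refined - count_original) / count_original


@dataclass(frozen=True)
class EvaluationReport:
    """Top-k evaluation of one ranking on one network."""

    method: str
    k: int
    tp: int
    fp: int
    precision: float
    portions: dict[str, float]
    roc: np.ndarray
    auc: float

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "tp": self.tp,
            "fp": self.fp,
            "precision": self.precision,
            "ess_ess": self.portions["ess_ess"],
            "ess_noness": self.portions["ess_noness"],
            "noness_noness": self.portions["noness_noness"],
            "auc": self.auc,
        }


def evaluate_ranking(
    net: PpiNetwork, result: centrality.CentralityResult, gold: GoldStandard, k: int = 600
) -> EvaluationReport:
    """Full per-method report: counts, precision, edge classes, ROC/AUC."""
    ranking = result.ranking
    tp = count_true_top_k(ranking, gold, k)
    n_pred = min(k, len(ranking))
    portions = edge_class_portions(net, ranking, gold, k)
    roc, auc = roc_auc(ranking, gold)
    return EvaluationReport(
        method=result.method,
        k=k,
        tp=tp,
        fp=n_pred - tp,
        precision=tp / n_pred,
        portions=portions,
        roc=roc,
        auc=auc,
    )


def threshold_sweep(
    net: PpiNetwork,
    scores: EdgeScoreTable,
    gold: GoldStandard,
    method: str = "DC",
    thresholds=(0.0, 0.1, 0.2, 0.33, 0.4, 0.5),
    ks=(100, 200, 300, 400, 500, 600),
) -> pd.DataFrame:
    """Refine at each threshold, rank, and count top-k true positives.

    Returns a long-format table with one row per (threshold, k).
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for tau in thresholds:
        refined, report = refine(net, scores, tau)
        if refined.n_nodes == 0:
            for k in ks:
                rows.append(
                    {"threshold": tau, "k": k, "n_true": 0, "n_proteins": 0,
                     "n_edges": 0}
                )
            continue
        result = centrality.compute(refined, method)
        for k in ks:
            rows.append(
                {
                    "threshold": tau,
                    "k": k,
                    "n_true": count_true_top_k(result.ranking, gold, k),
                    "n_proteins": refined.n_nodes,
                    "n_edges": report.n_reserved,
                }
            )
    return pd.DataFrame(rows)
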