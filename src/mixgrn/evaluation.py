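"""Ranked-network evaluation against a gold standard.

Follows the DREAM5 protocol: predictions are truncated to the top 100,000
edges, restricted to the pairs present in the gold-standard universe, and
treated as a binary classifier.  Gold pairs the method never predicted are
appended with score 0 (ranked after every prediction) so AUROC/AUPR are
computed over the full labeled universe.  Early precision and nDCG use
k = number of positive pairs in the gold standard.  Cross-network summary
scores are geometric means of per-network AUROC and AUPR; the overall
score is their arithmetic mean.  Tabulated values are reported to three
decimals with truncation toward zero, which is how the reference score
rows round (e.g. 0.3589 prints as 0.358).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io_formats import DEFAULT_EDGE_LIMIT, GoldStandard
from .network import RankedEdgeList


@dataclass
class EvaluationReport:
    auroc: float
    aupr: float
    ep_percent: float
    ndcg: float
    k_used: int
    n_true_positives_in_gold: int

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "ep_percent": self.ep_percent,
            "ndcg": self.ndcg,
            "k_used": self.k_used,
            "n_true_positives_in_gold": self.n_true_positives_in_gold,
        }


@dataclass
class ScoreSummary:
    per_network: list[tuple[float, float]]
    auroc_score: float
    aupr_score: float
    overall_score: float

    def truncated(self, decimals: int = 3) -> dict[str, float]:
        """Report values truncated toward zero at ``decimals`` places."""
        return {
            "auroc_score": truncate(self.auroc_score, decimals),
            "aupr_score": truncate(self.aupr_score, decimals),
            "overall_score": truncate(self.overall_score, decimals),
        }


def truncate(value: float, decimals: int = 3) -> float:
    """Truncate toward zero at ``decimals`` decimal places."""
    factor = 10.0 ** decimals
    return math.trunc(round(value * factor, 9)) / factor


def _ranked_labels(
    edges: RankedEdgeList, gold: GoldStandard, top_limit: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-ordered (labels, scores) over the gold universe.

    Predictions outside the universe are ignored; gold pairs never
    predicted are appended with score 0 in lexicographic order
    (deterministic worst rank).
    """
    universe = gold.labels
    seen = set()
    labels, scores = [], []
    for tf, tg, sc in edges.records[:top_limit]:
        pair = (tf, tg)
        if pair in universe and pair not in seen and tf != tg:
            seen.add(pair)
            labels.append(universe[pair])
            scores.append(sc)
    for pair in sorted(universe):
        if pair not in seen and pair[0] != pair[1]:
            labels.append(universe[pair])
            scores.append(0.0)
    return np.asarray(labels, int), np.asarray(scores, float)


def evaluate_ranking(
    edges: RankedEdgeList,
    gold: GoldStandard,
    top_limit: int = DEFAULT_EDGE_LIMIT,
) -> EvaluationReport:
    """AUROC, AUPR, early precision and nDCG of a ranked edge list.

    AUROC is the Mann-Whitney statistic (midrank ties); AUPR is step-wise
    precision-recall integration (no trapezoid interpolation).
    """
    labels, scores = _ranked_labels(edges, gold, top_limit)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("gold universe needs at least one positive and one negative")
    auroc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    k = int(labels.sum())
    hits_topk = int(labels[:k].sum())
    ep = 100.0 * hits_topk / k
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, k + 1))
    dcg = sum(
        1.0 / math.log2(i + 1) for i, lab in enumerate(labels[:k], start=1) if lab
    )
    return EvaluationReport(
        auroc=auroc,
        aupr=aupr,
        ep_percent=ep,
        ndcg=dcg / idcg,
        k_used=k,
        n_true_positives_in_gold=gold.n_positives,
    )


def early_precision(
    edges: RankedEdgeList,
    gold: GoldStandard,
    top_limit: int = DEFAULT_EDGE_LIMIT,
) -> float:
    """Percent of true positives among the top-k predictions (k = #positives)."""
    labels, _ = _ranked_labels(edges, gold, top_limit)
    k = int(labels.sum())
    if k == 0:
        raise ValueError("gold standard has no positive pairs")
    return 100.0 * float(labels[:k].sum()) / k


def ndcg_score(
    edges: RankedEdgeList,
    gold: GoldStandard,
    top_limit: int = DEFAULT_EDGE_LIMIT,
) -> float:
    """Normalized discounted cumulative gain over the top-k ranks."""
    labels, _ = _ranked_labels(edges, gold, top_limit)
    k = int(labels.sum())
    if k == 0:
        raise ValueError("gold standard has no positive pairs")
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, k + 1))
    dcg = sum(
        1.0 / math.log2(i + 1) for i, lab in enumerate(labels[:k], start=1) if lab
    )
    return dcg / idcg


def network_scores(per_network: list[tuple[float, float]]) -> ScoreSummary:
    """Cross-network geometric-mean scores and their arithmetic overall mean."""
    if not per_network:
        raise ValueError("need at least one (auroc, aupr) pair")
    aurocs = np.array([a for a, _ in per_network], float)
    auprs = np.array([p for _, p in per_network], float)
    if np.any(aurocs <= 0) or np.any(auprs <= 0) or np.any(aurocs > 1) or np.any(auprs > 1):
        raise ValueError("per-network metrics must lie in (0, 1]")
    auroc_score = float(np.exp(np.mean(np.log(aurocs))))
    aupr_score = float(np.exp(np.mean(np.log(auprs))))
    return ScoreSummary(
        per_network=list(per_network),
        auroc_score=auroc_score,
        aupr_score=aupr_score,
        overall_score=0.5 * (auroc_score + aupr_score),
    )
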