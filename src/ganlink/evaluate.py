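"""Ranking metrics for held-out-edge recovery: AUROC, AUPRC, NDCG.

The evaluation universe is the set of scored candidate pairs:
positives are held-out edges that received a confidence, negatives are
all other scored pairs.  Held-out edges that no subgraph could see are
reported separately in the coverage accounting; a strict mode appends
them with confidence zero so they count against the curves instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from sklearn.metrics import average_precision_score, roc_auc_score

from .network_io import Pair, PredictionRecord
from .predict import CoverageReport


@dataclass(frozen=True)
class MetricsReport:
    auroc: float
    auprc: float
    ndcg: float
    n_positives_scored: int
    n_candidates: int
    coverage: CoverageReport | None = field(default=None, compare=False)


def _labels_scores(records: Sequence[PredictionRecord], positives: set[Pair]):
    if len({r.pair for r in records}) != len(records):
        raise ValueError("records contain duplicate pairs")
    y_true = [1 if r.pair in positives else 0 for r in records]
    y_score = [r.confidence for r in records]
    return y_true, y_score


def auroc(records: Sequence[PredictionRecord], positives: set[Pair]) -> float:
    """Probability that a random scored positive outranks a random
    scored negative, ties counted one half (Mann-Whitney statistic)."""
    y_true, y_score = _labels_scores(records, positives)
    n_pos = sum(y_true)
    if n_pos == 0 or n_pos == len(y_true):
        raise ValueError("AUROC undefined without both scored positives and negatives")
    return float(roc_auc_score(y_true, y_score))


def auprc(records: Sequence[PredictionRecord], positives: set[Pair]) -> float:
    """Area under the precision-recall step curve (average precision)."""
    y_true, y_score = _labels_scores(records, positives)
    if sum(y_true) == 0:
        raise ValueError("AUPRC undefined without scored positives")
    return float(average_precision_score(y_true, y_score))


def ndcg(records: Sequence[PredictionRecord], positives: set[Pair]) -> float:
    """Normalized discounted cumulative gain with binary relevance,
    log2 discount and no rank truncation; 0 when nothing is relevant."""
    ranked = sorted(records, key=lambda r: (-r.confidence, r.pair))
    dcg = 0.0
    p = 0
    for rank, rec in enumerate(ranked, start=1):
        if rec.pair in positives:
            dcg += 1.0 / math.log2(rank + 1)
            p += 1
    if p == 0:
        return 0.0
    idcg = sum(1.0 / math.log2(r + 1) for r in range(1, p + 1))
    return dcg / idcg


def evaluate_fold(
    records: Sequence[PredictionRecord],
    removed_edges: set[Pair],
    coverage: CoverageReport | None = None,
    strict: bool = False,
) -> MetricsReport:
    """Score one fold's ranked predictions against its held-out edges.

    strict=False (default): only held-out edges that received a score
    enter the curves; the unscored remainder shows up in the coverage
    report.  strict=True: unscored held-out edges are appended with
    confidence 0 and count as missed positives.
    """
    records = list(records)
    scored_pairs = {r.pair for r in records}
    positives_scored = removed_edges & scored_pairs
    if strict:
        missing = sorted(removed_edges - scored_pairs)
        records = records + [
            PredictionRecord(pair=p, confidence=0.0) for p in missing
        ]
        records.sort(key=lambda r: (-r.confidence, r.pair))
        eval_positives = removed_edges & {r.pair for r in records}
    else:
        eval_positives = positives_scored
    return MetricsReport(
        auroc=auroc(records, eval_positives),
        auprc=auprc(records, eval_positives),
        ndcg=ndcg(records, eval_positives),
        n_positives_scored=len(positives_scored),
        n_candidates=len(records),
        coverage=coverage,
    )


def summarize(reports: Sequence[MetricsReport]) -> dict:
    """Arithmetic mean of per-fold metrics (cross-validation summary)."""
    n = len(reports)
    if n == 0:
        raise ValueError("no fold reports to summarize")
    return {
        "auroc": sum(r.auroc for r in reports) / n,
        "auprc": sum(r.auprc for r in reports) / n,
        "ndcg": sum(r.ndcg for r in reports) / n,
        "n_folds": n,
    }
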