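"""Evaluation metrics for imbalanced essential-protein prediction.

Average precision (the step-wise area under the precision-recall curve) is
the primary metric: with essential proteins rare, ROC AUC alone hides poor
positive-class behaviour. The top-fraction protocol mirrors how centrality
baselines are scored in this field: the top ``fraction`` of proteins by
score — typically the species' essential-protein proportion — is labelled
positive and confusion metrics are computed from that labelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricReport", "compute_metrics", "top_fraction_eval", "write_report"]


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    auc_roc: float
    average_precision: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc_roc": self.auc_roc,
            "average_precision": self.average_precision,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def _threshold_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float, float]:
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return accuracy, precision, recall, f


def compute_metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> MetricReport:
    """Ranking metrics (AUC with tie credit, step-wise AP) plus confusion
    metrics at the given score threshold. Requires both classes present."""
    y_true = np.asarray(y_true).ravel().astype(int)
    scores = np.asarray(scores, dtype=float).ravel()
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC/AP undefined: only one class present")
    auc = float(roc_auc_score(y_true, scores))
    ap = float(average_precision_score(y_true, scores))
    y_pred = (scores >= threshold).astype(int)
    tp, fp, tn, fn = _confusion(y_true, y_pred)
    accuracy, precision, recall, f = _threshold_metrics(tp, fp, tn, fn)
    return MetricReport(accuracy, precision, recall, f, auc, ap, tp, fp, tn, fn)


def top_fraction_eval(
    scores: np.ndarray,
    y_true: np.ndarray,
    fraction: float,
    proteins: Sequence[str] | None = None,
) -> MetricReport:
    """Label the top ceil(fraction * n) proteins by score as positive.

    Score ties are broken by protein ID (ascending) so the cut is
    deterministic. Ranking metrics are computed from the scores themselves.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float).ravel()
    y_true = np.asarray(y_true).ravel().astype(int)
    n = scores.size
    ids = list(proteins) if proteins is not None else [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-scores[i], ids[i]))
    k = math.ceil(fraction * n)
    y_pred = np.zeros(n, dtype=int)
    y_pred[order[:k]] = 1
    tp, fp, tn, fn = _confusion(y_true, y_pred)
    accuracy, precision, recall, f = _threshold_metrics(tp, fp, tn, fn)
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
        ap = float(average_precision_score(y_true, scores))
    else:
        auc = ap = float("nan")
    return MetricReport(accuracy, precision, recall, f, auc, ap, tp, fp, tn, fn)


def write_report(reports: dict[str, MetricReport], sink: IO[str]) -> None:
    """TSV report, one row per variant."""
    cols = [
        "variant",
        "accuracy",
        "precision",
        "recall",
        "f_measure",
        "auc_roc",
        "average_precision",
        "tp",
        "fp",
        "tn",
        "fn",
    ]
    sink.write("\t".join(cols) + "\n")
    for name, rep in reports.items():
        d = rep.as_dict()
        sink.write(name + "\t" + "\t".join(format(d[c], ".6g") for c in cols[1:]) + "\n")
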