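"""Confusion-matrix metrics and ROC/PR curves for model evaluation.

Balanced holdouts measure raw discriminability; 1:10 unbalanced holdouts
stress precision, where the PR curve (and auPRC) is the informative
summary. Curve points come from scikit-learn's threshold sweeps; areas
are trapezoidal. The PR curve's recall-0 endpoint reuses the precision at
the highest threshold (no interpolation to (0, 1)) — auPRC values depend
on this convention, so it is fixed here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "confusion_metrics",
    "roc_pr_curves",
    "EvaluationReport",
    "evaluate_model",
    "threshold_at_recall",
]


def confusion_metrics(
    truth: Sequence[int], predicted: Sequence[int]
) -> dict[str, float | int | None]:
    """TP/TN/FP/FN plus accuracy, precision, recall.

    Positive class = 1 (regulatory). Ratios with zero denominators are
    reported as None (undefined), never as 0.
    """
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and prediction vectors differ in length")
    if not (set(np.unique(t)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    total = tp + tn + fp + fn
    return {
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
        "accuracy": (tp + tn) / total if total else None,
        "precision": tp / (tp + fp) if (tp + fp) else None,
        "recall": tp / (tp + fn) if (tp + fn) else None,
    }


def roc_pr_curves(
    truth: Sequence[int], scores: Sequence[float]
) -> dict[str, np.ndarray | float]:
    """ROC and PR points over all score thresholds, with trapezoidal areas."""
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("both classes must be present to draw curves")
    fpr, tpr, roc_thr = roc_curve(t, s, drop_intermediate=False)
    au_roc = float(np.trapezoid(tpr, fpr))

    precision, recall, pr_thr = precision_recall_curve(t, s)
    # sklearn appends an artificial (recall 0, precision 1) endpoint;
    # replace its precision with the value at the highest threshold.
    if len(precision) >= 2:
        precision = precision.copy()
        precision[-1] = precision[-2]
    au_prc = float(np.trapezoid(precision[::-1], recall[::-1]))
    return {
        "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
        "precision": precision, "recall": recall, "pr_thresholds": pr_thr,
        "auROC": au_roc, "auPRC": au_prc,
    }


def threshold_at_recall(
    truth: Sequence[int], scores: Sequence[float], target_recall: float = 0.6
) -> tuple[float, float, float]:
    """Highest score threshold whose recall still reaches ``target_recall``.

    Returns (threshold, precision, recall) at that operating point — the
    stringency-calibration used before scanning a genome.
    """
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    precision, recall, thresholds = precision_recall_curve(t, s)
    # thresholds[i] corresponds to precision[i], recall[i]; recall is
    # non-increasing along thresholds, so take the last index meeting it.
    ok = np.nonzero(recall[:-1] >= target_recall)[0]
    if len(ok) == 0:
        raise ValueError(f"no threshold reaches recall {target_recall}")
    i = ok[-1]
    return float(thresholds[i]), float(precision[i]), float(recall[i])


@dataclass
class EvaluationReport:
    """Full evaluation of one model on one holdout."""

    ratio: int
    n_regulatory: int
    n_control: int
    confusion: dict
    auROC: float
    auPRC: float
    curves: dict = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "ratio": self.ratio,
            "n_regulatory": self.n_regulatory,
            "n_control": self.n_control,
            "confusion": self.confusion,
            "auROC": self.auROC,
            "auPRC": self.auPRC,
            "curves": {
                key: np.asarray(val).tolist() for key, val in self.curves.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        payload = json.loads(text)
        payload["curves"] = {
            key: np.asarray(val) for key, val in payload["curves"].items()
        }
        return cls(**payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def evaluate_model(
    scores: Sequence[float],
    truth: Sequence[int],
    ratio: int = 1,
    prob_threshold: float = 0.5,
) -> EvaluationReport:
    """Evaluate per-record P(regulatory) scores against truth labels.

    ``prob_threshold`` converts scores into calls for the confusion
    matrix (calibrated thresholds such as 0.85/0.95 are passed
    explicitly; 0.5 is the default decision rule).
    """
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    calls = (s >= prob_threshold).astype(int)
    conf = confusion_metrics(t, calls)
    curves = roc_pr_curves(t, s)
    return EvaluationReport(
        ratio=ratio,
        n_regulatory=int(t.sum()),
        n_control=int((t == 0).sum()),
        confusion=conf,
        auROC=curves["auROC"],
        auPRC=curves["auPRC"],
        curves={
            "fpr": curves["fpr"], "tpr": curves["tpr"],
            "precision": curves["precision"], "recall": curves["recall"],
        },
    )
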