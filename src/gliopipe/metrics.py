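"""Confusion-count bookkeeping and the evaluation metric battery.

All reported metrics derive from one-vs-rest TP/FP/TN/FN counts:

    accuracy   = (TP + TN) / total        sensitivity = recall = TPR
    precision  = TP / (TP + FP)                       = TP / (TP + FN)
    specificity= TN / (TN + FP)           FPR  = FP / (FP + TN)
    F1         = 2 * precision * recall / (precision + recall)

``detection_rate`` is reported as TP / total (the overall hit rate); it is
reported separately from TPR, so it is deliberately not another alias for
recall — a documented choice, since the term has no single standard
definition. Ratios with a zero denominator are
reported as NaN and listed under ``undefined`` rather than coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num, den):
    return num / den if den > 0 else math.nan


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Full metric report for one confusion table; NaN where undefined."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = counts.total
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    report = {
        "accuracy": _ratio(tp + tn, total),
        "sensitivity": recall,
        "specificity": _ratio(tn, tn + fp),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "detection_rate": _ratio(tp, total),
        "tpr": recall,
        "fpr": _ratio(fp, fp + tn),
    }
    report["undefined"] = sorted(
        k for k, v in report.items() if isinstance(v, float) and math.isnan(v)
    )
    return report


def confusion_from_labels(y_true, y_pred, classes=None) -> dict:
    """One-vs-rest confusion counts per class plus micro aggregate.

    Returns ``{class: ConfusionCounts, ..., "micro": ConfusionCounts}``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    out = {}
    micro = ConfusionCounts()
    for c in classes:
        t = y_true == c
        p = y_pred == c
        cc = ConfusionCounts(
            tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
        )
        out[c] = cc
        micro = ConfusionCounts(
            micro.tp + cc.tp, micro.fp + cc.fp, micro.tn + cc.tn,
            micro.fn + cc.fn,
        )
    out["micro"] = micro
    return out


def classification_report(y_true, y_pred, classes=None) -> dict:
    """Per-class, micro and macro metric report for a label vector pair."""
    counts = confusion_from_labels(y_true, y_pred, classes=classes)
    per_class = {
        str(c): compute_metrics(cc) for c, cc in counts.items() if c != "micro"
    }
    macro = {}
    keys = [k for k in next(iter(per_class.values())) if k != "undefined"]
    for k in keys:
        vals = [m[k] for m in per_class.values() if not math.isnan(m[k])]
        macro[k] = float(np.mean(vals)) if vals else math.nan
    return {
        "per_class": per_class,
        "micro": compute_metrics(counts["micro"]),
        "macro": macro,
        "overall_accuracy": float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
    }


def mask_overlap(mask_a, mask_b) -> float:
    """Intersection-over-union of two binary masks (NaN if both empty)."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    union = np.sum(a | b)
    return float(np.sum(a & b) / union) if union else math.nan
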