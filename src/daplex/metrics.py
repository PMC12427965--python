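"""Evaluation metrics for the binary diagnostic task.

Positive class is 1 (pneumonia). Seven metrics are tracked throughout:
sensitivity, specificity, precision, balanced accuracy (BA), F1,
ROC-AUC and the Brier score. A metric whose denominator is undefined
(e.g. no positives in a subgroup stratum) is reported as NaN — flagged
undefined, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "METRIC_NAMES", "LOSS_METRICS", "ConfusionCounts",
    "confusion_counts", "threshold_metrics", "roc_auc", "brier",
    "all_metrics", "aggregate_cv", "MetricReport",
]

METRIC_NAMES = (
    "balanced_accuracy", "sensitivity", "specificity",
    "precision", "f1", "roc_auc", "brier",
)
#: metrics where lower is better
LOSS_METRICS = frozenset({"brier"})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(int)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with class 1 (pneumonia) as positive."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def threshold_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Threshold-based metrics from a confusion table.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); BA = (sensitivity+specificity)/2;
    F1 = 2*precision*recall/(precision+recall). Undefined ratios → NaN.
    """
    sens = _ratio(cc.tp, cc.tp + cc.fn)
    spec = _ratio(cc.tn, cc.tn + cc.fp)
    prec = _ratio(cc.tp, cc.tp + cc.fp)
    ba = (sens + spec) / 2.0
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan") if (np.isnan(prec) or np.isnan(sens)) else 0.0
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "balanced_accuracy": ba, "f1": f1}


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all
    positive × negative pairs; ties handled by midranks. Returns NaN
    (flagged undefined) when only one class is present.
    """
    t = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("y_true and scores lengths differ")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    r_pos = ranks[t == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def brier(y_true, probs) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    t = _as_binary(y_true, "y_true")
    p = np.asarray(probs, dtype=float)
    if t.shape != p.shape:
        raise ValueError("y_true and probs lengths differ")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - t) ** 2))


def all_metrics(y_true, y_pred, probs) -> dict[str, float]:
    """All seven tracked metrics from hard predictions and probabilities."""
    out = threshold_metrics(confusion_counts(y_true, y_pred))
    out["roc_auc"] = roc_auc(y_true, probs)
    out["brier"] = brier(y_true, probs)
    return {name: out[name] for name in METRIC_NAMES}


@dataclass(frozen=True)
class MetricReport:
    """Mean and sample SD of each metric across CV folds."""

    means: dict[str, float]
    sds: dict[str, float]
    n_folds: int

    def to_dict(self) -> dict:
        return {name: {"mean": self.means[name], "sd": self.sds[name],
                       "n_folds": self.n_folds} for name in self.means}


def aggregate_cv(per_fold: list[dict[str, float]]) -> MetricReport:
    """Aggregate per-fold metric dicts to mean ± sample SD (ddof=1)."""
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds")
    keys = set(per_fold[0])
    if any(set(f) != keys for f in per_fold[1:]):
        raise ValueError("inconsistent metric sets across folds")
    means, sds = {}, {}
    for k in per_fold[0]:
        vals = np.array([f[k] for f in per_fold], dtype=float)
        means[k] = float(np.mean(vals))
        sds[k] = float(np.std(vals, ddof=1))
    return MetricReport(means=means, sds=sds, n_folds=len(per_fold))
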