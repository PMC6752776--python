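"""Evaluation of the binary laterality classifier.

All metrics treat the left eye as the positive class: sensitivity is the
true-positive rate on left-eye images, specificity the true-negative
rate on right-eye images.  Proportion confidence intervals use the
Wilson score method at 95%; the AUC interval uses the DeLong variance
estimator.  The ROC is a threshold sweep over the left-eye probability
P1 (an image is called LEFT when P1 >= t); the resulting trapezoidal
AUC equals the Mann-Whitney probability that a random left-eye score
exceeds a random right-eye score, ties counting one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

from .classifier import predict
from .synth_fundus import LEFT, RIGHT

__all__ = [
    "ConfusionMatrix",
    "MetricWithCI",
    "EvalReport",
    "confusion",
    "binary_metrics",
    "roc_auc",
    "evaluate_model",
]


class UndefinedMetricError(ValueError):
    """A stratum needed by the metric is empty."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    value: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: MetricWithCI
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    auc: MetricWithCI
    roc_points: list[tuple[float, float]]

    def to_dict(self, digits: int = 4) -> dict:
        r = lambda v: round(float(v), digits)
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
            },
            "accuracy": r(self.accuracy.value),
            "accuracy_ci": [r(v) for v in self.accuracy.ci],
            "sensitivity": r(self.sensitivity.value),
            "sensitivity_ci": [r(v) for v in self.sensitivity.ci],
            "specificity": r(self.specificity.value),
            "specificity_ci": [r(v) for v in self.specificity.ci],
            "auc": r(self.auc.value),
            "auc_ci": [r(v) for v in self.auc.ci],
            "roc": [[r(fpr), r(tpr)] for fpr, tpr in self.roc_points],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _is_left(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return arr == LEFT
    return arr == 0


def confusion(predictions, truths) -> ConfusionMatrix:
    """2x2 counts with LEFT as the positive class."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and truths must be equal-length and nonempty")
    p, t = _is_left(pred), _is_left(true)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fn=int(np.sum(~p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
    )


def _wilson(successes: int, n: int) -> MetricWithCI:
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return MetricWithCI(value=successes / n, ci=(float(lo), float(hi)))


def binary_metrics(cm: ConfusionMatrix) -> tuple[MetricWithCI, MetricWithCI, MetricWithCI]:
    """(accuracy, sensitivity, specificity), each with a Wilson 95% CI."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedMetricError("both classes must be present to compute metrics")
    return (
        _wilson(cm.tp + cm.tn, cm.total),
        _wilson(cm.tp, cm.tp + cm.fn),
        _wilson(cm.tn, cm.tn + cm.fp),
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (structural components)."""
    m, n = pos.size, neg.size
    both = np.concatenate([pos, neg])
    tz = _midrank(both)
    tx = _midrank(pos)
    ty = _midrank(neg)
    v01 = (tz[:m] - tx) / n                # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m          # per-negative placement values
    s01 = float(np.var(v01, ddof=1)) if m > 1 else 0.0
    s10 = float(np.var(v10, ddof=1)) if n > 1 else 0.0
    return s01 / m + s10 / n


def roc_auc(scores, truths) -> tuple[MetricWithCI, list[tuple[float, float]]]:
    """AUC (with DeLong 95% CI) and the full ROC sweep for left-eye scores."""
    s = np.asarray(scores, dtype=np.float64)
    t = _is_left(truths)
    if t.all() or not t.any():
        raise UndefinedMetricError("both classes must be present to compute an ROC")
    fpr, tpr, _ = roc_curve(t, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    var = _delong_variance(s[t], s[~t])
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return MetricWithCI(value=auc, ci=ci), list(zip(fpr.tolist(), tpr.tolist()))


def evaluate_model(model, images: np.ndarray, truths, out_csv: str | Path | None = None,
                   filenames=None) -> EvalReport:
    """Predict every image and assemble the full evaluation report.

    Labels use the 0.5 threshold on P1 with the LEFT tie-break (the same
    rule as :func:`fundus_laterality.classifier.predict`).
    """
    preds = [predict(model, images[i]) for i in range(images.shape[0])]
    labels = [p.label for p in preds]
    scores = [p.p_left for p in preds]
    cm = confusion(labels, truths)
    accuracy, sensitivity, specificity = binary_metrics(cm)
    auc, roc_points = roc_auc(scores, truths)
    if out_csv is not None:
        truth_labels = [LEFT if b else RIGHT for b in _is_left(truths)]
        pd.DataFrame(
            {
                "filename": filenames if filenames is not None else range(len(preds)),
                "p_left": [p.p_left for p in preds],
                "p_right": [p.p_right for p in preds],
                "pred": labels,
                "truth": truth_labels,
            }
        ).to_csv(out_csv, index=False)
    return EvalReport(
        confusion=cm,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        roc_points=roc_points,
    )
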