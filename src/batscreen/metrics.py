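"""Binary classification metrics for the screening task.

Positive class is 1 (screened positive).  Tp counts correct positive
predictions in truly positive respondents, Fp incorrect positive
predictions, Tn correct negatives and Fn missed positives.

    precision = Tp / (Tp + Fp)
    recall    = Tp / (Tp + Fn)
    accuracy  = (Tp + Tn) / (Tp + Fp + Tn + Fn)
    F1        = 2 * recall * precision / (recall + precision)

A metric with a zero denominator is reported as 0.0 with an explicit
``undefined`` flag instead of raising, so batch reports never abort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    return (0.0, True) if den == 0 else (num / den, False)


def precision(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp)[0]


def recall(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn)[0]


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total)[0]


def f1(cm: ConfusionMatrix) -> float:
    p, r = precision(cm), recall(cm)
    return _ratio(2.0 * r * p, r + p)[0]


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    tpr = _ratio(cm.tp, cm.tp + cm.fn)[0]
    tnr = _ratio(cm.tn, cm.tn + cm.fp)[0]
    return 0.5 * (tpr + tnr)


def metric_report(cm: ConfusionMatrix) -> dict:
    """All four headline metrics plus undefined-denominator flags."""
    out = {}
    for name, num, den in (
        ("precision", cm.tp, cm.tp + cm.fp),
        ("recall", cm.tp, cm.tp + cm.fn),
        ("accuracy", cm.tp + cm.tn, cm.total),
    ):
        value, undefined = _ratio(num, den)
        out[name] = value
        out[f"{name}_undefined"] = undefined
    p, r = out["precision"], out["recall"]
    out["f1"], out["f1_undefined"] = _ratio(2 * p * r, p + r)
    return out


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding as printed in screening reports (0.005 -> 0.01)."""
    factor = 10.0 ** decimals
    return np.floor(x * factor + 0.5) / factor


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_points(y_true, scores) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs at thresholds set to the unique scores, descending.

    Starts at (0, 0) (threshold above every score) and ends at (1, 1).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores differ in length")
    P = int(np.sum(y_true == 1))
    N = int(np.sum(y_true == 0))
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present")
    points = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int(np.sum(pred & (y_true == 1)))
        fp = int(np.sum(pred & (y_true == 0)))
        points.append((fp / N, tp / P))
    return points


def auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under an ordered (FPR, TPR) curve."""
    pts = sorted(points)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return float(area)


def roc_auc(y_true, scores) -> float:
    return auc(roc_points(y_true, scores))
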