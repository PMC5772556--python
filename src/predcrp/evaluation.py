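"""Binary-classification metrics with the repressor as the positive class.

Sites on which CRP represses are the positives; activator sites are the
negatives.  ACC, SEN (recall on repressors), SPE (recall on activators)
and Matthews correlation coefficient are reported, plus ROC/AUC from
decision scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .selection import POSITIVE_CLASS


@dataclass
class ConfusionMetrics:
    TP: int
    FP: int
    TN: int
    FN: int
    positive_class: str = POSITIVE_CLASS

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def ACC(self) -> float:
        return (self.TP + self.TN) / self.n if self.n else 0.0

    @property
    def SEN(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def SPE(self) -> float:
        d = self.TN + self.FP
        return self.TN / d if d else 0.0

    @property
    def MCC(self) -> float:
        """Matthews correlation; 0 when the denominator vanishes."""
        num = self.TP * self.TN - self.FP * self.FN
        den = (
            (self.TP + self.FP)
            * (self.TP + self.FN)
            * (self.TN + self.FP)
            * (self.TN + self.FN)
        )
        return num / math.sqrt(den) if den else 0.0

    def rounded(self, digits: int = 2) -> dict:
        return {
            "SPE": round(self.SPE, digits),
            "SEN": round(self.SEN, digits),
            "MCC": round(self.MCC, digits),
            "ACC": round(self.ACC, digits),
        }

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "ACC": self.ACC,
            "SEN": self.SEN,
            "SPE": self.SPE,
            "MCC": self.MCC,
        }


def confusion_metrics(y_true, y_pred, positive: str = POSITIVE_CLASS) -> ConfusionMetrics:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} truths vs {len(y_pred)} predictions"
        )
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    return ConfusionMetrics(TP=tp, FP=fp, TN=tn, FN=fn, positive_class=positive)


def metrics_from_rates(
    n_pos: int, n_neg: int, sen: float, spe: float
) -> ConfusionMetrics:
    """Reconstruct a confusion matrix from class sizes and printed SEN/SPE
    (rounded to the nearest achievable integer counts)."""
    tp = int(round(sen * n_pos))
    tn = int(round(spe * n_neg))
    return ConfusionMetrics(TP=tp, FP=n_neg - tn, TN=tn, FN=n_pos - tp)


def roc_auc(
    scores, y_true, positive: str = POSITIVE_CLASS
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR) and trapezoid AUC.

    Tied scores are swept together, so the trapezoid area equals the
    rank-sum (Mann-Whitney) probability that a positive outscores a
    negative, counting ties as half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if t == positive else 0 for t in y_true])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("roc_auc needs at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
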