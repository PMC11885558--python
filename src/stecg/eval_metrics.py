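"""Confusion-matrix construction and classification metrics.

Reports the standard arrhythmia-classification suite: overall accuracy,
per-class sensitivity (Se, recall), positive predictive value (PPV,
precision) and F1, Cohen's kappa, and the Gorodkin multiclass Matthews
correlation coefficient.  Degenerate 0/0 cells evaluate to 0 (not NaN) so
per-class tables are always numeric; affected classes are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "per_class_metrics",
           "overall_accuracy", "cohen_kappa", "mcc_multiclass", "report"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # [K, K]; rows true, cols predicted
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    confusion: ConfusionMatrix
    overall_acc: float
    se: np.ndarray
    ppv: np.ndarray
    f1: np.ndarray
    kappa: float
    mcc: float
    degenerate_classes: tuple[int, ...] = ()

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        labels = (self.confusion.labels
                  or tuple(str(i) for i in range(self.confusion.counts.shape[0])))
        return {
            "overall_acc": self.overall_acc * scale,
            "kappa": self.kappa,
            "mcc": self.mcc,
            "per_class": {
                lab: {"Se": self.se[i] * scale, "PPV": self.ppv[i] * scale,
                      "F1": self.f1[i] * scale}
                for i, lab in enumerate(labels)},
            "confusion": self.confusion.counts.tolist(),
        }


def confusion(y_true, y_pred, K: int, labels=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and ((y_true.min() < 0) or (y_true.max() >= K)
                        or (y_pred.min() < 0) or (y_pred.max() >= K)):
        raise ValueError("label outside [0, K)")
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return ConfusionMatrix(cm, tuple(labels) if labels is not None else None)


def _cm(cm) -> np.ndarray:
    return cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)


def per_class_metrics(cm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (Se, PPV, F1); any 0/0 evaluates to 0."""
    c = _cm(cm).astype(float)
    tp = np.diag(c)
    row = c.sum(axis=1)   # tp + fn
    col = c.sum(axis=0)   # tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(row > 0, tp / row, 0.0)
        ppv = np.where(col > 0, tp / col, 0.0)
        denom = se + ppv
        f1 = np.where(denom > 0, 2 * se * ppv / denom, 0.0)
    return se, ppv, f1


def overall_accuracy(cm) -> float:
    c = _cm(cm)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(c) / total)


def cohen_kappa(cm) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e); defined as 0 when
    the expected agreement p_e equals 1."""
    c = _cm(cm).astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total ** 2
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def mcc_multiclass(cm) -> float:
    """Gorodkin's K-class Matthews correlation; 0 on degenerate marginals.

    Reduces exactly to the classical binary MCC on 2×2 matrices.
    """
    c = _cm(cm).astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    num = total * np.trace(c) - float(row @ col)
    den = np.sqrt((total ** 2 - float(row @ row))
                  * (total ** 2 - float(col @ col)))
    if den == 0:
        return 0.0
    return float(num / den)


def report(y_true, y_pred, K: int, labels=None) -> MetricReport:
    cm = confusion(y_true, y_pred, K, labels)
    se, ppv, f1 = per_class_metrics(cm)
    degenerate = tuple(int(i) for i in range(K)
                       if cm.counts[i].sum() == 0 and cm.counts[:, i].sum() == 0)
    return MetricReport(cm, overall_accuracy(cm), se, ppv, f1,
                        cohen_kappa(cm), mcc_multiclass(cm), degenerate)
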