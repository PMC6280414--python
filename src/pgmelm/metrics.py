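"""Evaluation metrics for imbalanced binary classification, plus kernel MMD
for scoring generated-sample quality.

Class 1 is the positive/minority class throughout.  Metrics with a zero
denominator are reported as ``None`` (undefined), never silently 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist


class UndefinedMetricError(ValueError):
    """Requested metric has no defined value (e.g. single-class labels)."""


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass
class MetricsReport:
    """TPR (= recall), TNR, precision, G-mean, F-measure; optionally AUC.

    G-mean = sqrt(TPR * TNR); F-measure = 2 * precision * recall /
    (precision + recall).  Undefined entries are None.
    """

    tpr: float | None
    tnr: float | None
    precision: float | None
    recall: float | None
    g_mean: float | None
    f_measure: float | None
    auc: float | None = None

    def to_json(self, cm: ConfusionMatrix | None = None) -> str:
        doc = asdict(self)
        if cm is not None:
            doc["confusion"] = asdict(cm)
        return json.dumps(doc, indent=2)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with class 1 positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.all(np.isin(arr, [0, 1])):
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def classification_report(cm: ConfusionMatrix) -> MetricsReport:
    """Derive TPR/TNR/precision/recall/G-mean/F-measure from counts."""
    tpr = _ratio(cm.tp, cm.tp + cm.fn)
    tnr = _ratio(cm.tn, cm.fp + cm.tn)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    g_mean = None if tpr is None or tnr is None else float(np.sqrt(tpr * tnr))
    if prec is None or tpr is None or prec + tpr == 0:
        f_meas = None
    else:
        f_meas = 2.0 * prec * tpr / (prec + tpr)
    return MetricsReport(tpr=tpr, tnr=tnr, precision=prec, recall=tpr,
                         g_mean=g_mean, f_measure=f_meas)


def roc_auc(scores, y_true) -> tuple[np.ndarray, float]:
    """ROC points by threshold sweep and AUC by the trapezoid rule.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counting one half.  Returns (points, auc) with
    points an array of (FPR, TPR) rows from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y_true[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def roc_points_csv(points: np.ndarray, path) -> None:
    """Write ROC points as a two-column CSV (FPR, TPR) for plotting."""
    np.savetxt(path, points, delimiter=",", header="fpr,tpr", comments="")


def kernel_mmd(X: np.ndarray, Y: np.ndarray,
               bandwidth: float | None = None) -> float:
    """Biased (V-statistic) two-sample MMD with a Gaussian kernel.

    k(x, y) = exp(-||x - y||^2 / (2 h^2)); ``bandwidth=None`` uses the
    median pairwise distance over the pooled sample.  The biased estimator
    guarantees MMD(X, X) = 0 exactly and nonnegativity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("need >= 2 samples in each set")
    if bandwidth is None:
        pooled = np.vstack([X, Y])
        d = cdist(pooled, pooled)
        med = np.median(d[np.triu_indices_from(d, k=1)])
        bandwidth = med if med > 1e-12 else 1.0
    gamma = 1.0 / (2.0 * bandwidth * bandwidth)
    kxx = np.exp(-gamma * cdist(X, X, "sqeuclidean")).mean()
    kyy = np.exp(-gamma * cdist(Y, Y, "sqeuclidean")).mean()
    kxy = np.exp(-gamma * cdist(X, Y, "sqeuclidean")).mean()
    return float(np.sqrt(max(kxx + kyy - 2.0 * kxy, 0.0)))
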