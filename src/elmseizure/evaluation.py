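"""Binary confusion matrix, the full metric panel, and ROC/AUC.

The panel mirrors the standard seizure-detection report: accuracy,
prevalence, precision, recall, F1, specificity, sensitivity and AUC, with
recall and sensitivity being the same quantity (both are emitted for schema
compatibility with reports that list the two side by side).

AUC is computed two independent ways: the ROC curve over all distinct score
thresholds (equal scores grouped into one step) integrated by the trapezoid
rule, and a Mann–Whitney pair count with half credit for ties, exposed as a
cross-check.  The two are mathematically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "confusion",
    "multiclass_confusion",
    "metrics",
    "roc_auc",
    "auc_pair_count",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def complemented(self) -> "ConfusionMatrix":
        """Confusion of the label-flipped predictions (swaps roles)."""
        return ConfusionMatrix(tp=self.fn, fp=self.tn, fn=self.tp, tn=self.fp)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    prevalence: float
    precision: float
    recall: float
    f1: float
    specificity: float
    sensitivity: float
    auc: float | None
    n_samples: int
    split_label: str = ""
    degenerate: tuple[str, ...] = ()   # metrics whose denominator was zero


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray   # descending
    fpr: np.ndarray          # nondecreasing, [0, 1]
    tpr: np.ndarray          # nondecreasing, [0, 1]


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary {0, 1}")
    return y.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Binary confusion counts with positive class = 1."""
    yt, yp = _check_binary(y_true), _check_binary(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def multiclass_confusion(y_true, y_pred, labels=None) -> np.ndarray:
    """K x K count matrix (rows = true, cols = predicted); correct counts on
    the diagonal.  Used for the pre-binarization five-class view."""
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    if yt.size == 0:
        raise ValueError("empty input")
    if labels is None:
        labels = np.unique(np.concatenate([yt, yp]))
    labels = np.asarray(labels)
    K = len(labels)
    M = np.zeros((K, K), dtype=int)
    pos = {c: i for i, c in enumerate(labels.tolist())}
    for t, p in zip(yt, yp):
        M[pos[t], pos[p]] += 1
    return M


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, auc: float | None = None, split_label: str = "") -> MetricsReport:
    """The full panel from a confusion matrix (AUC attached if supplied).

    Ratios with zero denominators are reported as 0 and flagged in
    ``degenerate`` rather than raising, so sweep loops never abort.
    """
    n = cm.n
    if n == 0:
        raise ValueError("confusion matrix has zero total count")
    deg: list[str] = []
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", deg)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", deg)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", deg)
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) > 0 else 0.0
    if (precision + recall) == 0:
        deg.append("f1")
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / n,
        prevalence=(cm.tp + cm.fn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        sensitivity=recall,
        auc=auc,
        n_samples=n,
        split_label=split_label,
        degenerate=tuple(deg),
    )


def roc_auc(y_true, scores) -> tuple[ROCCurve, float]:
    """ROC curve over all distinct thresholds + trapezoidal AUC.

    Equal scores are grouped into a single step (half-credit tie handling).
    Requires both classes present.
    """
    y = _check_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores lengths differ")
    P = int(y.sum())
    N = len(y) - P
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    ys, ss = y[order], s[order]
    # last index of each tie group
    last = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(ys)[last]
    fps = (last + 1) - tps
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    thresholds = np.r_[np.inf, ss[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr), auc


def auc_pair_count(y_true, scores) -> float:
    """Mann–Whitney AUC: fraction of positive–negative pairs correctly
    ordered, ties counted half.  Computed from rank sums."""
    y = _check_binary(y_true)
    s = np.asarray(scores, dtype=float)
    P = int(y.sum())
    N = len(y) - P
    if P == 0 or N == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks for ties
    U = ranks[y == 1].sum() - P * (P + 1) / 2
    return float(U / (P * N))


def plot_roc(curve: ROCCurve, auc: float | None = None, ax=None, label: str = "ELM"):
    """Basic ROC plot with the chance diagonal; needs matplotlib installed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    text = label if auc is None else f"{label} (AUC = {auc:.3f})"
    ax.plot(curve.fpr, curve.tpr, label=text)
    ax.plot([0, 1], [0, 1], "b--", linewidth=1, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    return ax
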