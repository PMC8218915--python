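"""Classification metrics and distance-based clustering for heatmaps.

Confusion-matrix summaries (ACC, F1, precision), threshold-swept ROC and
precision-recall curves with trapezoidal / step-wise areas, the Gini index
(2*AUC - 1), and Euclidean sample-distance matrices with average-linkage
leaf ordering for heatmap arrangement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class EvaluationReport:
    """Container for everything the pipeline reports about a prediction."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    acc: float | None = None
    f1: float | None = None
    pre: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    pr_points: list[tuple[float, float]] | None = None
    auc: float | None = None
    gini: float | None = None
    auc_pr: float | None = None
    distance_matrix: np.ndarray | None = None

    def metrics_dict(self) -> dict:
        return {
            "acc": self.acc, "f1": self.f1, "pre": self.pre,
            "auc": self.auc, "gini": self.gini, "auc_pr": self.auc_pr,
            "counts": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metrics_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _check_binary(*arrays):
    out = []
    for arr in arrays:
        arr = np.asarray(arr).astype(int)
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        out.append(arr)
    if len({a.size for a in out}) != 1:
        raise ValueError("label vectors must have equal length")
    return out


def confusion_metrics(y_true, y_pred) -> EvaluationReport:
    """Confusion counts plus ACC, F1 and precision.

    ACC = (TP+TN)/(TP+TN+FP+FN); F1 = 2TP/(2TP+FP+FN);
    PRE = TP/(TP+FP), reported as ``None`` when nothing is predicted
    positive (and F1 likewise when its denominator vanishes).
    """
    y_true, y_pred = _check_binary(y_true, y_pred)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None
    pre = tp / (tp + fp) if (tp + fp) else None
    return EvaluationReport(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, f1=f1, pre=pre)


def _threshold_sweep(y_true, scores):
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size != scores.size:
        raise ValueError("labels and scores must align")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    # one threshold per distinct score: predict positive when score >= t
    boundary = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    tps = np.cumsum(y_sorted)[boundary]
    fps = boundary + 1 - tps
    return tps, fps, int(y_true.sum()), int(y_true.size - y_true.sum())


def roc_curve(y_true, scores):
    """ROC points, trapezoidal AUC and Gini index (2*AUC - 1).

    Thresholds sweep the distinct scores in descending order (tied scores
    collapse to one threshold); the endpoints (0,0) and (1,1) are always
    included.
    """
    tps, fps, P, N = _threshold_sweep(y_true, scores)
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, auc, 2.0 * auc - 1.0


def pr_curve(y_true, scores):
    """Precision-recall points and step-wise interpolated area.

    The area is the sum of precision times recall increment over the
    descending-threshold sweep (average-precision convention).
    """
    tps, fps, P, _ = _threshold_sweep(y_true, scores)
    recall = tps / P
    precision = tps / (tps + fps)
    auc_pr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return list(zip(recall.tolist(), precision.tolist())), auc_pr


def euclidean_distance_matrix(values) -> np.ndarray:
    """Pairwise Euclidean distances between the columns (samples)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return squareform(pdist(values.T, metric="euclidean"))


def cluster_order(dist) -> np.ndarray:
    """Average-linkage hierarchical-clustering leaf order of the samples.

    Deterministic for a fixed distance matrix; used to arrange heatmap
    rows/columns so that similar samples are adjacent.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    if n == 1:
        return np.array([0])
    Z = linkage(squareform(dist, checks=False), method="average")
    return np.asarray(leaves_list(Z))


def evaluate_selection(y_true, scores, selected_values) -> EvaluationReport:
    """Full report for a selected gene subset.

    ``scores`` are held-out predicted probabilities for each sample,
    ``selected_values`` the genes x samples block of the selected subset
    (used for the sample distance matrix).
    """
    report = confusion_metrics(y_true, (np.asarray(scores) >= 0.5).astype(int))
    report.roc_points, report.auc, report.gini = roc_curve(y_true, scores)
    report.pr_points, report.auc_pr = pr_curve(y_true, scores)
    report.distance_matrix = euclidean_distance_matrix(selected_values)
    return report
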