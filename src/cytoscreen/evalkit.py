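"""Evaluation machinery for the screening pipeline.

Covers IoU-0.5 detection matching into a 3-truth-class x
(3-predicted + missing) confusion matrix, the binary screening metrics
(sensitivity, specificity, accuracy, PPV, NPV, F1, G-Mean), the
uninterpolated rectangle-rule PR-curve area, COCO-style per-class
AP/AR means at a fixed IoU threshold, and nonparametric model
comparisons (Friedman, pairwise exact Wilcoxon signed-rank with Holm
adjustment).

Missing-detection convention: a ground-truth cell with no matched
prediction counts as *predicted negative* -- it is a false negative when
its true class is positive and a true negative otherwise.  Spurious
detections (no ground-truth overlap) are tallied separately from the
3x4 matrix; they enter precision-style metrics (AP) as false positives
but not the screening tallies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon as ShapelyPolygon
from statsmodels.stats.multitest import multipletests

from cytoscreen.annotio import CLASSES, LabelSet

MISSING = "missing"
_PRED_COLUMNS = CLASSES + (MISSING,)


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bundled reference confusion matrices (published evaluation of a
# conventional-protocol model "T1" and an active-learning model "A3" on a
# shared cervical-cytology test set; rows = truth yin / yin-yang / yang,
# columns = predicted yin / yin-yang / yang / missing).
# ---------------------------------------------------------------------------

REFERENCE_CONFUSION_T1 = np.array(
    [[2839, 36, 17, 23],
     [0, 27, 15, 1],
     [1, 4, 100, 3]]
)

REFERENCE_CONFUSION_A3 = np.array(
    [[2851, 44, 18, 2],
     [0, 28, 15, 0],
     [1, 0, 106, 0]]
)


@dataclass
class ConfusionMatrix3M:
    """3 truth classes x (3 predicted + missing) counts, plus spurious."""

    counts: np.ndarray
    spurious: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 4):
            raise MetricError("confusion matrix must be 3x4 (truth x predicted+missing)")
        if (self.counts < 0).any() or self.spurious < 0:
            raise MetricError("confusion counts must be nonnegative")

    def truth_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def total_cells(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinaryTally:
    """TP/TN/FP/FN under the missing-as-predicted-negative policy."""

    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class PRCurve:
    """A precision-recall curve swept over score thresholds (descending)."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.recall) < -1e-12):
            raise MetricError("recall must be non-decreasing along the sweep")


# ---------------------------------------------------------------------------
# Detection matching
# ---------------------------------------------------------------------------

def _poly_iou(a, b) -> float:
    pa = ShapelyPolygon(np.asarray(a)).buffer(0)
    pb = ShapelyPolygon(np.asarray(b)).buffer(0)
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    truth: LabelSet,
    detections: Sequence,
    iou_threshold: float = 0.5,
) -> tuple[list[tuple[int, int, float]], ConfusionMatrix3M]:
    """Greedily match detections to ground truth and tally the confusion.

    Detections are visited in descending confidence; each claims the
    unmatched truth nucleus of highest IoU if that IoU reaches the
    threshold.  Matched pairs contribute to cell (truth class, predicted
    class); unmatched truth lands in the ``missing`` column; unmatched
    detections are tallied separately as spurious.

    Returns (assignment, matrix) where assignment lists
    ``(detection_index, truth_index, iou)`` pairs.
    """
    if not 0 < iou_threshold <= 1:
        raise MetricError("iou_threshold must be in (0, 1]")
    det_order = sorted(
        range(len(detections)), key=lambda i: (-detections[i].score, i)
    )
    unmatched = set(range(len(truth.annotations)))
    assignment = []
    counts = np.zeros((3, 4), dtype=int)
    spurious = 0
    for di in det_order:
        det = detections[di]
        best, best_iou = None, iou_threshold
        for ti in unmatched:
            iou = _poly_iou(det.polygon, truth.annotations[ti].polygon)
            if iou >= best_iou:
                best, best_iou = ti, iou
        if best is None:
            spurious += 1
            continue
        unmatched.discard(best)
        assignment.append((di, best, best_iou))
        counts[CLASSES.index(truth.annotations[best].cls), CLASSES.index(det.cls)] += 1
    for ti in unmatched:
        counts[CLASSES.index(truth.annotations[ti].cls), 3] += 1
    return assignment, ConfusionMatrix3M(counts=counts, spurious=spurious)


def pool_confusions(matrices: Sequence[ConfusionMatrix3M]) -> ConfusionMatrix3M:
    """Sum per-image confusion matrices into one test-set matrix."""
    total = np.zeros((3, 4), dtype=int)
    spurious = 0
    for m in matrices:
        total += m.counts
        spurious += m.spurious
    return ConfusionMatrix3M(counts=total, spurious=spurious)


# ---------------------------------------------------------------------------
# Binary screening metrics
# ---------------------------------------------------------------------------

def binary_tally(cm: ConfusionMatrix3M, positive_classes: Sequence[str]) -> BinaryTally:
    pos = [CLASSES.index(c) for c in positive_classes]
    if not pos:
        raise MetricError("positive_classes must be a nonempty subset of the classes")
    neg = [i for i in range(3) if i not in pos]
    pred_pos_cols = pos  # missing column (3) counts as predicted negative
    c = cm.counts
    tp = int(c[np.ix_(pos, pred_pos_cols)].sum())
    fn = int(c[pos, :].sum() - tp)
    fp = int(c[np.ix_(neg, pred_pos_cols)].sum()) if neg else 0
    tn = int(c[neg, :].sum() - fp) if neg else 0
    return BinaryTally(tp=tp, tn=tn, fp=fp, fn=fn)


def binary_metrics(
    cm: ConfusionMatrix3M,
    positive_classes: Sequence[str],
    percent: bool = True,
) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, PPV and NPV for a positive set.

    A cell of a positive class predicted as *any* positive class is a
    TP; predicted negative or missed, an FN.  A negative-class cell
    predicted positive is an FP; predicted negative or missed, a TN.
    Zero-denominator metrics are reported as None rather than NaN.
    """
    t = binary_tally(cm, positive_classes)
    scale = 100.0 if percent else 1.0

    def _ratio(num, den):
        if den == 0:
            warnings.warn("metric undefined (zero denominator)", RuntimeWarning)
            return None
        return scale * num / den

    total = t.tp + t.tn + t.fp + t.fn
    return {
        "sensitivity": _ratio(t.tp, t.tp + t.fn),
        "specificity": _ratio(t.tn, t.tn + t.fp),
        "accuracy": _ratio(t.tp + t.tn, total),
        "ppv": _ratio(t.tp, t.tp + t.fp),
        "npv": _ratio(t.tn, t.fn + t.tn),
    }


def f1_gmean(precision: float, recall: float, specificity: float) -> tuple[float, float]:
    """F1 = harmonic mean of precision and recall; G-Mean = sqrt(recall * specificity).

    Inputs on [0, 1].  F1 is defined as 0 when precision + recall = 0.
    """
    for name, v in (("precision", precision), ("recall", recall), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise MetricError(f"{name} must be in [0, 1]")
    if precision + recall == 0:
        warnings.warn("F1 undefined (precision + recall = 0); reporting 0", RuntimeWarning)
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return f1, float(np.sqrt(recall * specificity))


# ---------------------------------------------------------------------------
# PR curves
# ---------------------------------------------------------------------------

def pr_curve_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[PRCurve, float]:
    """Uninterpolated PR curve and its rectangle-rule area.

    Thresholds sweep the unique scores in descending order; at each, the
    instances with score >= threshold are predicted positive.  The area
    is the sum of ``(R_n - R_{n-1}) * P_n`` with R_0 = 0 -- no
    interpolation of any kind.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise MetricError("scores and labels must align")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricError("PR curve needs at least one positive instance")
    thresholds = np.unique(scores)[::-1]
    recall, precision = [], []
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        recall.append(tp / n_pos)
        precision.append(tp / int(pred.sum()))
    recall = np.asarray(recall)
    precision = np.asarray(precision)
    auc = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return PRCurve(recall=recall, precision=precision, thresholds=thresholds), auc


def detection_pr_auc(
    truth_sets: Sequence[LabelSet],
    detection_lists: Sequence[Sequence],
    iou_threshold: float = 0.5,
) -> tuple[PRCurve, float]:
    """PR-AUC of correct nucleus classification over the score sweep.

    A detection is *correct* when it matches a ground-truth nucleus at
    the IoU threshold with the right class.  Recall is against all
    ground-truth nuclei; precision against all detections above each
    threshold; area by the rectangle rule.
    """
    scores, correct = [], []
    n_truth = 0
    for ls, dets in zip(truth_sets, detection_lists):
        n_truth += len(ls.annotations)
        assignment, _ = match_detections(ls, dets, iou_threshold)
        matched_class_ok = {
            di for di, ti, _ in assignment
            if dets[di].cls == ls.annotations[ti].cls
        }
        for di, d in enumerate(dets):
            scores.append(d.score)
            correct.append(1 if di in matched_class_ok else 0)
    if n_truth == 0:
        raise MetricError("no ground-truth nuclei in the test set")
    if not scores:
        empty = PRCurve(recall=np.zeros(1), precision=np.zeros(1), thresholds=np.zeros(1))
        return empty, 0.0
    scores = np.asarray(scores)
    correct = np.asarray(correct)
    thresholds = np.unique(scores)[::-1]
    recall, precision = [], []
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (correct == 1)).sum())
        recall.append(tp / n_truth)
        precision.append(tp / int(pred.sum()))
    recall = np.asarray(recall)
    precision = np.asarray(precision)
    auc = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return PRCurve(recall=recall, precision=precision, thresholds=thresholds), auc


# ---------------------------------------------------------------------------
# COCO-style mAP / mAR at one IoU threshold
# ---------------------------------------------------------------------------

def map_mar(
    truth_sets: Sequence[LabelSet],
    detection_lists: Sequence[Sequence],
    iou_threshold: float = 0.5,
    percent: bool = True,
) -> dict:
    """Mean average precision and recall over classes at a fixed IoU.

    Per class, detections of that class across all images are swept in
    descending score and greedily matched (per image) to unmatched
    ground-truth nuclei of the same class; AP is the rectangle-rule area
    of the resulting PR points, AR the final recall.  Spurious
    detections count as false positives.  Classes with no ground truth
    are excluded with a warning.
    """
    per_class_ap, per_class_ar = {}, {}
    for cls in CLASSES:
        entries = []  # (score, image_index, det_index)
        n_truth = 0
        for img_idx, (ls, dets) in enumerate(zip(truth_sets, detection_lists)):
            n_truth += sum(1 for a in ls.annotations if a.cls == cls)
            for di, d in enumerate(dets):
                if d.cls == cls:
                    entries.append((d.score, img_idx, di))
        if n_truth == 0:
            warnings.warn(f"class {cls!r} has no ground-truth instances; excluded")
            continue
        entries.sort(key=lambda e: (-e[0], e[1], e[2]))
        matched: dict[int, set[int]] = {i: set() for i in range(len(truth_sets))}
        tp_flags = []
        for score, img_idx, di in entries:
            ls = truth_sets[img_idx]
            det = detection_lists[img_idx][di]
            best, best_iou = None, iou_threshold
            for ti, ann in enumerate(ls.annotations):
                if ann.cls != cls or ti in matched[img_idx]:
                    continue
                iou = _poly_iou(det.polygon, ann.polygon)
                if iou >= best_iou:
                    best, best_iou = ti, iou
            if best is None:
                tp_flags.append(0)
            else:
                matched[img_idx].add(best)
                tp_flags.append(1)
        tp_cum = np.cumsum(tp_flags)
        ranks = np.arange(1, len(tp_flags) + 1)
        recall = tp_cum / n_truth
        precision = tp_cum / ranks
        ap = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
        per_class_ap[cls] = ap
        per_class_ar[cls] = float(recall[-1]) if len(recall) else 0.0
    if not per_class_ap:
        raise MetricError("no class has any ground-truth instances")
    scale = 100.0 if percent else 1.0
    return {
        "mAP": scale * float(np.mean(list(per_class_ap.values()))),
        "mAR": scale * float(np.mean(list(per_class_ar.values()))),
        "per_class_AP": {k: scale * v for k, v in per_class_ap.items()},
        "per_class_AR": {k: scale * v for k, v in per_class_ar.items()},
    }


# ---------------------------------------------------------------------------
# Nonparametric model comparisons
# ---------------------------------------------------------------------------

def friedman_compare(metric_matrix: np.ndarray) -> dict:
    """Friedman rank test across methods over shared CV folds.

    ``metric_matrix`` is methods x folds.  Methods are ranked within
    each fold (average ranks on ties); the tie-corrected chi-square
    statistic and its asymptotic p-value are returned with the mean
    rank per method (rank 1 = best, i.e. highest metric).
    """
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise MetricError("need >= 3 methods and >= 2 folds")
    k, n = m.shape
    # rank within each fold, descending metric -> rank 1 best
    ranks = np.empty_like(m)
    tie_term = 0.0
    for j in range(n):
        ranks[:, j] = stats.rankdata(-m[:, j], method="average")
        _, t_counts = np.unique(m[:, j], return_counts=True)
        tie_term += float(np.sum(t_counts**3 - t_counts))
    mean_ranks = ranks.mean(axis=1)
    rank_sums = ranks.sum(axis=1)
    statistic = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        warnings.warn("all methods tied in every fold", RuntimeWarning)
        return {"statistic": 0.0, "p_value": 1.0, "mean_ranks": mean_ranks, "tied": True}
    statistic /= correction
    p = float(stats.chi2.sf(statistic, k - 1))
    return {
        "statistic": float(statistic),
        "p_value": p,
        "mean_ranks": mean_ranks,
        "tied": bool(np.isclose(statistic, 0.0)),
    }


def wilcoxon_pairwise(
    metric_matrix: np.ndarray,
    method_names: Sequence[str] | None = None,
) -> list[dict]:
    """Pairwise Wilcoxon signed-rank tests with Holm adjustment.

    Uses the exact signed-rank null distribution for n <= 25 pairs
    (zero differences dropped, Wilcoxon's convention).  Each result dict
    carries the raw and Holm-adjusted two-sided p-values; a pair with
    all-zero differences reports p = 1 with a flag.
    """
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise MetricError("need >= 2 methods")
    names = list(method_names) if method_names else [f"method{i}" for i in range(m.shape[0])]
    results = []
    for i, j in itertools.combinations(range(m.shape[0]), 2):
        diff = m[i] - m[j]
        if np.all(diff == 0):
            results.append(
                {"pair": (names[i], names[j]), "p_raw": 1.0, "all_zero": True}
            )
            continue
        nz = diff[diff != 0]
        mode = "exact" if len(nz) <= 25 else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.wilcoxon(
                m[i], m[j], zero_method="wilcox", alternative="two-sided", method=mode
            )
        results.append(
            {"pair": (names[i], names[j]), "statistic": float(stat),
             "p_raw": float(p), "all_zero": False}
        )
    raw = [r["p_raw"] for r in results]
    _, adjusted, _, _ = multipletests(raw, method="holm")
    for r, p_adj in zip(results, adjusted):
        r["p_holm"] = float(min(p_adj, 1.0))
    return results
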