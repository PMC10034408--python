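"""Evaluation machinery: matching, screening metrics, PR curves, AP means,
and the nonparametric model comparisons, each checked against an
independent brute-force oracle where one exists."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from cytoscreen.annotio import CLASSES, LabelSet, NucleusAnnotation
from cytoscreen.cellnet import Detection
from cytoscreen.evalkit import (
    ConfusionMatrix3M,
    MetricError,
    REFERENCE_CONFUSION_A3,
    REFERENCE_CONFUSION_T1,
    binary_metrics,
    binary_tally,
    detection_pr_auc,
    f1_gmean,
    friedman_compare,
    map_mar,
    match_detections,
    pool_confusions,
    pr_curve_auc,
    wilcoxon_pairwise,
)


def _circle(cx, cy, r, n=20):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)


def _det(image_id, cx, cy, r, cls, score):
    probs = np.full(3, (1 - score) / 2)
    probs[CLASSES.index(cls)] = score
    return Detection(image_id, _circle(cx, cy, r), cls, probs / probs.sum())


def _truth_set(cells):
    anns = [NucleusAnnotation("img", _circle(cx, cy, r), cls) for cx, cy, r, cls in cells]
    return LabelSet("img", 200, 200, anns)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

class TestMatchDetections:
    def test_perfect_predictions_give_diagonal_matrix(self):
        truth = _truth_set([(30, 30, 8, "yin"), (80, 30, 8, "yin-yang"), (30, 80, 8, "yang")])
        dets = [
            _det("img", 30, 30, 8, "yin", 0.9),
            _det("img", 80, 30, 8, "yin-yang", 0.9),
            _det("img", 30, 80, 8, "yang", 0.9),
        ]
        _, cm = match_detections(truth, dets)
        assert np.array_equal(cm.counts, np.diag([1, 1, 1]) @ np.eye(3, 4, dtype=int))
        assert cm.counts[:, 3].sum() == 0
        assert cm.spurious == 0

    def test_no_predictions_all_missing(self):
        truth = _truth_set([(30, 30, 8, "yin"), (80, 30, 8, "yang")])
        _, cm = match_detections(truth, [])
        assert cm.counts[:, :3].sum() == 0
        assert cm.counts[0, 3] == 1 and cm.counts[2, 3] == 1

    def test_higher_score_wins_contested_truth(self):
        # two candidates over one nucleus: the higher-score one matches,
        # the other is spurious -- confirmed by enumerating all one-to-one
        # assignments on a 3-cell toy
        truth = _truth_set([(30, 30, 8, "yin"), (90, 30, 8, "yang"), (150, 30, 8, "yin")])
        dets = [
            _det("img", 31, 30, 8, "yin", 0.6),
            _det("img", 29, 30, 8, "yin-yang", 0.9),  # same nucleus, higher score
            _det("img", 90, 30, 8, "yang", 0.8),
            _det("img", 150, 30, 8, "yin", 0.7),
        ]
        assignment, cm = match_detections(truth, dets)
        matched_dets = {di for di, _, _ in assignment}
        assert 1 in matched_dets and 0 not in matched_dets
        assert cm.spurious == 1

        # oracle: among all injective detection->truth assignments with
        # IoU >= 0.5, greedy-by-score must match the one that assigns
        # each contested truth to its highest-score candidate
        from cytoscreen.evalkit import _poly_iou

        feasible = {}
        for di, d in enumerate(dets):
            for ti, t in enumerate(truth.annotations):
                if _poly_iou(d.polygon, t.polygon) >= 0.5:
                    feasible.setdefault(ti, []).append(di)
        for ti, candidates in feasible.items():
            best = max(candidates, key=lambda di: dets[di].score)
            assert (best, ti) in {(a, b) for a, b, _ in assignment}

    def test_threshold_validation(self):
        truth = _truth_set([(30, 30, 8, "yin")])
        with pytest.raises(MetricError, match="iou_threshold"):
            match_detections(truth, [], iou_threshold=0.0)

    def test_row_sums_equal_truth_counts(self):
        truth = _truth_set(
            [(30, 30, 8, "yin"), (80, 30, 8, "yin"), (30, 80, 8, "yang"), (130, 80, 9, "yin-yang")]
        )
        dets = [_det("img", 30, 30, 8, "yang", 0.9), _det("img", 130, 80, 9, "yin-yang", 0.8)]
        _, cm = match_detections(truth, dets)
        assert cm.counts.sum(axis=1).tolist() == [2, 1, 1]


# ---------------------------------------------------------------------------
# Binary screening metrics
# ---------------------------------------------------------------------------

class TestBinaryMetrics:
    def test_published_active_model_composite_metrics(self):
        cm = ConfusionMatrix3M(REFERENCE_CONFUSION_A3)
        m = binary_metrics(cm, ["yin-yang", "yang"])
        assert m["sensitivity"] == pytest.approx(99.33, abs=0.005)
        assert m["specificity"] == pytest.approx(97.87, abs=0.005)
        assert m["accuracy"] == pytest.approx(97.94, abs=0.005)

    def test_published_conventional_model_yin_metrics(self):
        cm = ConfusionMatrix3M(REFERENCE_CONFUSION_T1)
        m = binary_metrics(cm, ["yin"])
        assert m["sensitivity"] == pytest.approx(97.39, abs=0.005)
        assert m["accuracy"] == pytest.approx(97.49, abs=0.005)

    def test_all_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix3M(np.array([[5, 0, 0, 0], [0, 4, 0, 0], [0, 0, 3, 0]]))
        for positives in (["yin"], ["yin-yang", "yang"]):
            m = binary_metrics(cm, positives)
            assert all(v == pytest.approx(100.0) for v in m.values())

    def test_missing_counts_as_predicted_negative(self):
        # one yin missed: TN for abnormal-positive tally, FN for yin tally
        cm = ConfusionMatrix3M(np.array([[0, 0, 0, 1], [0, 1, 0, 0], [0, 0, 1, 0]]))
        t_abn = binary_tally(cm, ["yin-yang", "yang"])
        assert (t_abn.tp, t_abn.tn, t_abn.fp, t_abn.fn) == (2, 1, 0, 0)
        t_yin = binary_tally(cm, ["yin"])
        assert (t_yin.tp, t_yin.fn) == (0, 1)

    def test_zero_denominator_flags_none(self):
        cm = ConfusionMatrix3M(np.array([[0, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]]))
        with pytest.warns(RuntimeWarning):
            m = binary_metrics(cm, ["yin"])
        assert m["sensitivity"] is None

    def test_empty_positive_set_rejected(self):
        cm = ConfusionMatrix3M(np.zeros((3, 4), dtype=int))
        with pytest.raises(MetricError, match="nonempty"):
            binary_metrics(cm, [])

    @given(st.lists(st.integers(0, 50), min_size=12, max_size=12))
    def test_metrics_bounded_on_random_matrices(self, flat):
        cm = ConfusionMatrix3M(np.array(flat).reshape(3, 4))
        if cm.total_cells() == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for positives in (["yin"], ["yang"], ["yin-yang", "yang"]):
                for v in binary_metrics(cm, positives).values():
                    assert v is None or 0.0 <= v <= 100.0


class TestF1GMean:
    def test_perfect_scores(self):
        assert f1_gmean(1.0, 1.0, 1.0) == (1.0, 1.0)

    def test_zero_recall_gives_zero_f1(self):
        f1, _ = f1_gmean(1.0, 0.0, 1.0)
        assert f1 == 0.0

    def test_degenerate_zero_precision_and_recall_flagged(self):
        with pytest.warns(RuntimeWarning):
            f1, _ = f1_gmean(0.0, 0.0, 1.0)
        assert f1 == 0.0

    def test_gmean_is_square_root_of_product(self):
        _, g = f1_gmean(0.5, 0.9, 0.4)
        assert g == pytest.approx(0.6)

    def test_range_validation(self):
        with pytest.raises(MetricError):
            f1_gmean(1.2, 0.5, 0.5)


# ---------------------------------------------------------------------------
# PR curves
# ---------------------------------------------------------------------------

def _brute_force_pr_auc(scores, labels):
    """Independent rectangle-rule oracle: direct tally at each threshold."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    prev_recall = 0.0
    auc = 0.0
    for t in sorted(set(scores), reverse=True):
        tp = fp = 0
        for s, l in zip(scores, labels):
            if s >= t:
                if l == 1:
                    tp += 1
                else:
                    fp += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return auc


class TestPrCurveAuc:
    def test_perfect_separation_gives_unit_auc(self):
        _, auc = pr_curve_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(1000) < 0.3).astype(int)
        scores = rng.random(1000)
        _, auc = pr_curve_auc(scores, labels)
        assert auc == pytest.approx(labels.mean(), abs=0.05)

    def test_four_point_toy_matches_enumeration(self):
        scores, labels = [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        _, auc = pr_curve_auc(scores, labels)
        assert auc == pytest.approx(_brute_force_pr_auc(scores, labels))

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = rng.integers(2, 51)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[rng.integers(n)] = 1
            scores = rng.choice(np.round(rng.random(10), 3), size=n)  # with ties
            _, auc = pr_curve_auc(scores, labels)
            assert auc == pytest.approx(_brute_force_pr_auc(scores, labels), abs=1e-12)
            assert 0.0 <= auc <= 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError, match="positive"):
            pr_curve_auc([0.5, 0.4], [0, 0])


# ---------------------------------------------------------------------------
# mAP / mAR
# ---------------------------------------------------------------------------

class TestMapMar:
    def test_single_class_perfect_detections(self):
        truth = _truth_set([(30, 30, 8, "yin"), (90, 30, 8, "yin")])
        dets = [_det("img", 30, 30, 8, "yin", 0.9), _det("img", 90, 30, 8, "yin", 0.8)]
        with pytest.warns(UserWarning):  # two classes absent from truth
            res = map_mar([truth], [dets])
        assert res["mAP"] == pytest.approx(100.0)
        assert res["mAR"] == pytest.approx(100.0)

    def test_one_perfect_one_missed_class_averages_to_half(self):
        truth = _truth_set([(30, 30, 8, "yin"), (90, 30, 8, "yang")])
        dets = [_det("img", 30, 30, 8, "yin", 0.9)]
        with pytest.warns(UserWarning):
            res = map_mar([truth], [dets])
        assert res["mAP"] == pytest.approx(50.0)

    def test_hand_computed_three_class_toy(self):
        # yin: dets scores .9 (TP), .7 (FP) over 1 truth ->
        #   PR points (1, 1.0), (1, 0.5): AP = 1.0
        # yang: dets .8 (FP), .6 (TP) over 1 truth -> AP = 0.5
        # yin-yang: one truth, no dets -> AP = 0
        truth = _truth_set([(30, 30, 8, "yin"), (90, 30, 8, "yang"), (150, 150, 8, "yin-yang")])
        dets = [
            _det("img", 30, 30, 8, "yin", 0.9),
            _det("img", 150, 30, 8, "yin", 0.7),
            _det("img", 30, 150, 8, "yang", 0.8),
            _det("img", 90, 30, 8, "yang", 0.6),
        ]
        res = map_mar([truth], [dets])
        assert res["per_class_AP"]["yin"] == pytest.approx(100.0)
        assert res["per_class_AP"]["yang"] == pytest.approx(50.0)
        assert res["per_class_AP"]["yin-yang"] == pytest.approx(0.0)
        assert res["mAP"] == pytest.approx((100 + 50 + 0) / 3)

    def test_all_classes_empty_rejected(self):
        with pytest.raises(MetricError):
            with pytest.warns(UserWarning):
                map_mar([LabelSet("img", 64, 64, [])], [[]])


class TestDetectionPrAuc:
    def test_perfect_detection_set(self):
        truth = _truth_set([(30, 30, 8, "yin"), (90, 30, 8, "yang")])
        dets = [_det("img", 30, 30, 8, "yin", 0.9), _det("img", 90, 30, 8, "yang", 0.8)]
        _, auc = detection_pr_auc([truth], [dets])
        assert auc == pytest.approx(1.0)

    def test_missed_truth_caps_recall(self):
        truth = _truth_set([(30, 30, 8, "yin"), (90, 30, 8, "yang")])
        dets = [_det("img", 30, 30, 8, "yin", 0.9)]
        curve, auc = detection_pr_auc([truth], [dets])
        assert curve.recall[-1] == pytest.approx(0.5)
        assert auc == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Friedman / Wilcoxon
# ---------------------------------------------------------------------------

def _brute_force_friedman(matrix):
    """Independent ranking oracle (no tie correction; valid when no ties)."""
    m = np.asarray(matrix, dtype=float)
    k, n = m.shape
    ranks = np.zeros_like(m)
    for j in range(n):
        order = sorted(range(k), key=lambda i: -m[i, j])
        for rank, i in enumerate(order, start=1):
            ranks[i, j] = rank
    rank_sums = ranks.sum(axis=1)
    return (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)


class TestFriedman:
    def test_strict_dominance_gives_clean_ranks_and_small_p(self):
        folds = 10
        m = np.array([
            np.linspace(0.9, 0.95, folds),
            np.linspace(0.8, 0.85, folds),
            np.linspace(0.7, 0.75, folds),
        ])
        res = friedman_compare(m)
        assert res["mean_ranks"].tolist() == [1.0, 2.0, 3.0]
        assert res["p_value"] < 0.01
        assert res["statistic"] == pytest.approx(2 * folds)  # closed form k=3 strict

    def test_identical_methods_statistic_zero(self):
        m = np.ones((3, 5))
        with pytest.warns(RuntimeWarning):
            res = friedman_compare(m)
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_toy_table_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(3)
        m = rng.random((3, 4))  # no ties almost surely
        res = friedman_compare(m)
        assert res["statistic"] == pytest.approx(_brute_force_friedman(m))
        stat, p = sps.friedmanchisquare(*m.T.T)
        assert res["statistic"] == pytest.approx(stat)
        assert res["p_value"] == pytest.approx(p)

    def test_shape_validation(self):
        with pytest.raises(MetricError):
            friedman_compare(np.ones((2, 5)))


def _exact_wilcoxon_p(diff):
    """Enumerate all sign patterns of |differences| (two-sided)."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        m = np.vstack([np.arange(8.0), np.arange(8.0)])
        res = wilcoxon_pairwise(m)
        assert res[0]["p_raw"] == 1.0
        assert res[0]["all_zero"]

    def test_all_positive_differences_n10_exact_p(self):
        a = np.arange(10.0) + 1.0
        b = a - 0.5
        res = wilcoxon_pairwise(np.vstack([a, b]))
        assert res[0]["p_raw"] == pytest.approx(2 / 1024)

    def test_exact_p_matches_sign_pattern_enumeration(self):
        rng = np.random.default_rng(8)
        a = rng.random(8)
        b = a + rng.normal(0, 0.5, 8)
        res = wilcoxon_pairwise(np.vstack([a, b]))
        assert res[0]["p_raw"] == pytest.approx(_exact_wilcoxon_p(a - b))

    def test_holm_never_decreases_p(self):
        rng = np.random.default_rng(9)
        m = rng.random((4, 10))
        for r in wilcoxon_pairwise(m):
            assert r["p_holm"] >= r["p_raw"] - 1e-15


class TestPoolConfusions:
    def test_pooling_sums_counts_and_spurious(self):
        a = ConfusionMatrix3M(np.ones((3, 4), dtype=int), spurious=2)
        b = ConfusionMatrix3M(2 * np.ones((3, 4), dtype=int), spurious=1)
        pooled = pool_confusions([a, b])
        assert (pooled.counts == 3).all()
        assert pooled.spurious == 3
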