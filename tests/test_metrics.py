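"""Evaluation machinery: matching rules, P/R arithmetic, AP vs a
brute-force cut-point oracle, mAP aggregation."""

import numpy as np
import pytest

from dragoneye import metrics as M


def ds(pred_boxes, conf, gt_boxes, pred_cls=None, gt_cls=None):
    pred_boxes = np.asarray(pred_boxes, float).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, float).reshape(-1, 4)
    return M.DetectionSet(
        pred_boxes, conf,
        pred_cls if pred_cls is not None else np.zeros(len(pred_boxes)),
        gt_boxes,
        gt_cls if gt_cls is not None else np.zeros(len(gt_boxes)),
    )


def brute_force_ap(tp_flags, confs, n_gt):
    """Independent all-point AP: enumerate every confidence cut-point,
    collect (recall, precision) operating points, integrate the envelope
    max precision at recall >= r over recall increments.  O(n^2)."""
    order = np.argsort(-np.asarray(confs), kind="stable")
    tp = np.asarray(tp_flags, bool)[order]
    pts = []
    for k in range(1, len(tp) + 1):
        t = tp[:k].sum()
        pts.append((t / n_gt, t / k))
    pts = sorted(set(pts))
    ap, prev_r = 0.0, 0.0
    for r, _ in pts:
        if r > prev_r:
            env = max(p for rr, p in pts if rr >= r)
            ap += (r - prev_r) * env
            prev_r = r
    return 100.0 * ap


class TestMatch:
    def test_exact_hit(self):
        d = ds([[5, 5, 2, 2]], [0.9], [[5, 5, 2, 2]])
        tp, _, fn = M.match(d)
        assert tp.tolist() == [True] and fn == 0

    def test_single_match_rule(self):
        d = ds([[5, 5, 2, 2], [5.1, 5, 2, 2]], [0.9, 0.8], [[5, 5, 2, 2]])
        tp, _, fn = M.match(d)
        assert tp.sum() == 1 and fn == 0

    def test_missed_ground_truth(self):
        d = ds(np.zeros((0, 4)), [], [[1, 1, 2, 2], [5, 5, 2, 2], [9, 9, 2, 2]])
        tp, _, fn = M.match(d)
        assert len(tp) == 0 and fn == 3

    def test_threshold_bounds(self):
        d = ds([[5, 5, 2, 2]], [0.9], [[5, 5, 2, 2]])
        with pytest.raises(ValueError):
            M.match(d, 0.0)


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fn,expect",
        [((True,) * 9 + (False,), 3, (90.0, 75.0)),
         ((True, True), 0, (100.0, 100.0)),
         ((), 5, (0.0, 0.0))],
        ids=["mixed", "perfect", "none"],
    )
    def test_arithmetic(self, tp, fn, expect):
        assert M.precision_recall(np.array(tp, bool), fn) == pytest.approx(expect)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        curve = M.pr_curve(np.array([True, True, True]), np.array([0.9, 0.8, 0.7]), 3)
        assert curve.ap == pytest.approx(100.0)

    def test_half_recall_perfect_precision(self):
        curve = M.pr_curve(np.array([True]), np.array([0.9]), 2)
        assert curve.ap == pytest.approx(50.0)

    def test_recall_nondecreasing(self, rng):
        curve = M.pr_curve(rng.random(50) < 0.5, rng.random(50), 30)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_monotone_confidence_transform_invariance(self, rng):
        flags = rng.random(40) < 0.6
        confs = rng.random(40)
        a = M.pr_curve(flags, confs, 30).ap
        b = M.pr_curve(flags, confs ** 3, 30).ap  # strictly monotone remap
        assert a == pytest.approx(b)

    def test_false_positive_never_helps_true_positive_never_hurts(self, rng):
        flags = rng.random(20) < 0.5
        confs = rng.random(20)
        base = M.pr_curve(flags, confs, 15).ap
        worse = M.pr_curve(np.append(flags, False), np.append(confs, 0.5), 15).ap
        better = M.pr_curve(np.append(flags, True), np.append(confs, 1.1 * confs.max()), 15).ap
        assert worse <= base + 1e-12
        assert better >= base - 1e-12

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 25))
            n_gt = int(rng.integers(1, 20))
            flags = rng.random(n) < rng.random()
            if flags.sum() > n_gt:
                flags[np.where(flags)[0][n_gt:]] = False
            confs = np.round(rng.random(n), 2)  # ties included
            got = M.pr_curve(flags, confs, n_gt).ap
            want = brute_force_ap(flags, confs, n_gt)
            assert got == pytest.approx(want, abs=1e-9)

    def test_empty_curve(self):
        assert M.pr_curve(np.zeros(0, bool), np.zeros(0), 0).ap == 0.0


class TestMeanAP:
    def test_single_class_equals_ap(self):
        assert M.mean_ap([97.4]) == pytest.approx(97.4)

    def test_two_class_mean(self):
        assert M.mean_ap([100.0, 0.0]) == pytest.approx(50.0)

    def test_bounded_by_extremes(self, rng):
        aps = rng.uniform(0, 100, size=7)
        assert aps.min() <= M.mean_ap(aps) <= aps.max()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            M.mean_ap([])


class TestEvaluate:
    def test_ground_truth_as_predictions_is_perfect(self, rng):
        sets = []
        for _ in range(5):
            gt = rng.uniform(10, 90, size=(4, 2))
            boxes = np.concatenate([gt, rng.uniform(5, 15, size=(4, 2))], axis=1)
            sets.append(ds(boxes, np.ones(4), boxes))
        rep = M.evaluate(sets)
        assert rep["map"] == pytest.approx(100.0)
        assert rep["precision"] == pytest.approx(100.0)
        assert rep["recall"] == pytest.approx(100.0)

    def test_no_predictions_gives_zero(self):
        rep = M.evaluate([ds(np.zeros((0, 4)), [], [[5, 5, 2, 2]])])
        assert rep["map"] == 0.0
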