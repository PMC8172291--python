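import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import morphology

from vesselseg.metrics import (
    CALReport,
    ConfusionCounts,
    basic_metrics,
    cal_metrics,
    confusion_counts,
    evaluate_pair,
    mcc,
)


def brute_force_confusion(pred, gt, region):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if not region[i, j]:
                continue
            if pred[i, j] and gt[i, j]:
                tp += 1
            elif pred[i, j]:
                fp += 1
            elif gt[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


class TestConfusionCounts:
    def test_perfect_and_inverted(self, rng):
        gt = rng.uniform(size=(10, 10)) > 0.5
        c = confusion_counts(gt, gt)
        assert c.fp == 0 and c.fn == 0
        c = confusion_counts(~gt, gt)
        assert c.tp == 0 and c.tn == 0

    def test_hand_fixture_matches_pixel_loop(self):
        gt = np.zeros((3, 3), bool)
        gt[0, 0] = gt[1, 1] = True
        pred = np.zeros((3, 3), bool)
        pred[1, 1] = True       # one hit
        pred[2, 2] = True       # one false alarm
        region = np.ones((3, 3), bool)
        c = confusion_counts(pred, gt, region)
        assert (c.tp, c.fp, c.tn, c.fn) == brute_force_confusion(pred, gt, region)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 6, 1)

    def test_region_restriction(self, rng):
        pred = rng.uniform(size=(8, 8)) > 0.5
        gt = rng.uniform(size=(8, 8)) > 0.5
        region = np.zeros((8, 8), bool)
        region[:4] = True
        c = confusion_counts(pred, gt, region)
        assert c.total == 32

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.ones((2, 2), bool), np.ones((2, 2), bool),
                             np.zeros((2, 2), bool))


class TestBasicMetrics:
    def test_perfect_prediction_all_ones(self):
        rep = basic_metrics(ConfusionCounts(tp=10, fp=0, tn=20, fn=0))
        assert rep.se == rep.sp == rep.acc == rep.auc == 1.0

    def test_hand_arithmetic(self):
        rep = basic_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert rep.se == pytest.approx(0.6)
        assert rep.sp == pytest.approx(0.8)
        assert rep.acc == pytest.approx(0.7)
        assert rep.auc == pytest.approx(0.7)

    def test_fusion_row_balanced_accuracy(self):
        # published fusion operating point: Se 0.8745, Sp 0.9624
        assert (0.8745 + 0.9624) / 2 == pytest.approx(0.91845)
        assert round((0.8745 + 0.9624) / 2, 4) == 0.9185 or abs((0.8745 + 0.9624) / 2 - 0.9185) <= 5e-5

    def test_zero_denominator_marks_nan_not_raise(self):
        rep = basic_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert math.isnan(rep.se)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 1000)] * 4))
    def test_auc_is_balanced_accuracy_identity(self, counts):
        c = ConfusionCounts(*counts)
        rep = basic_metrics(c)
        assert rep.auc == pytest.approx((rep.se + rep.sp) / 2)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(0, 1000)] * 4))
    def test_acc_invariant_under_class_swap(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        a = basic_metrics(ConfusionCounts(tp, fp, tn, fn)).acc
        b = basic_metrics(ConfusionCounts(tn, fn, tp, fp)).acc
        assert a == pytest.approx(b)


class TestMCC:
    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(tp=0, fp=5, tn=0, fn=5)) == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        value = mcc(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert value == pytest.approx((12 - 2) / math.sqrt(4 * 5 * 5 * 6))

    def test_zero_marginal_convention(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=5, fn=0)) == 0.0

    def test_printed_variant_differs(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert mcc(c, printed_variant=True) == pytest.approx((12 - 6) / math.sqrt(4 * 5 * 5 * 6))


def brute_force_dilate(mask, radius):
    out = np.zeros_like(mask)
    offs = [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if morphology.disk(radius)[dy + radius, dx + radius]]
    ys, xs = np.where(mask)
    for y, x in zip(ys, xs):
        for dy, dx in offs:
            yy, xx = y + dy, x + dx
            if 0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]:
                out[yy, xx] = True
    return out


class TestCAL:
    def test_identical_masks_score_one(self):
        s = np.zeros((20, 20), bool)
        s[5:15, 10] = True
        rep = cal_metrics(s, s)
        assert rep.c == rep.a == rep.l == rep.cal == 1.0

    def test_empty_prediction_zero_area_hence_zero_cal(self):
        s_g = np.zeros((10, 10), bool)
        s_g[4, 2:8] = True
        rep = cal_metrics(np.zeros((10, 10), bool), s_g)
        assert rep.a == 0.0 and rep.cal == 0.0

    def test_fragmenting_a_line_lowers_connectivity_per_closed_form(self):
        # ground truth: one 18-px horizontal line; prediction: same pixels
        # minus two gap pixels -> three 8-connected fragments
        s_g = np.zeros((9, 24), bool)
        s_g[4, 3:21] = True
        assert s_g.sum() == 18
        s = s_g.copy()
        s[4, 8] = s[4, 14] = False
        rep = cal_metrics(s, s_g)
        assert rep.c == pytest.approx(1.0 - abs(1 - 3) / 18)
        assert rep.c < cal_metrics(s_g, s_g).c
        # area term recomputed by direct set operations
        a_num = (brute_force_dilate(s, 2) & s_g) | (brute_force_dilate(s_g, 2) & s)
        assert rep.a == pytest.approx(a_num.sum() / (s | s_g).sum())
        assert rep.cal == pytest.approx(rep.c * rep.a * rep.l)

    def test_length_term_via_direct_skeleton_sets(self):
        s_g = np.zeros((16, 16), bool)
        s_g[5:11, 5:8] = True
        s = np.zeros_like(s_g)
        s[6:12, 5:8] = True  # shifted by one row
        rep = cal_metrics(s, s_g)
        phi_s = morphology.skeletonize(s)
        phi_g = morphology.skeletonize(s_g)
        num = (phi_s & brute_force_dilate(s_g, 2)) | (brute_force_dilate(s, 2) & phi_g)
        assert rep.l == pytest.approx(num.sum() / (phi_s | phi_g).sum())

    def test_cal_bounded_by_factors(self, rng):
        s = rng.uniform(size=(24, 24)) > 0.8
        s_g = np.zeros((24, 24), bool)
        s_g[6:18, 12] = True
        rep = cal_metrics(s, s_g)
        assert rep.cal <= min(max(rep.c, 0), max(rep.a, 0), max(rep.l, 0)) + 1e-12

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            cal_metrics(np.ones((4, 4), bool), np.zeros((4, 4), bool))


def test_evaluate_pair_returns_full_report(rng):
    gt = np.zeros((32, 32), bool)
    gt[10:20, 15] = True
    pred = gt.copy()
    pred[12, 15] = False
    out = evaluate_pair(pred, gt)
    assert {"se", "sp", "acc", "auc", "mcc", "c", "a", "l", "cal"} <= set(out)
    assert 0 < out["se"] < 1 and out["cal"] <= 1
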