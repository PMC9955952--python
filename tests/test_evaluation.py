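"""Metric formulas against hand-computed values and counting invariants."""

import numpy as np
import pytest

from piradscaps.evaluation import (
    CUTOFFS,
    ConfusionCounts,
    Cutoff,
    EvalFinding,
    aggregate_dice,
    binary_counts,
    dice_coefficient,
    interslice_consistency,
    match_and_count,
    metrics_from_counts,
)


def _vol(shape=(2, 8, 8)):
    return np.zeros(shape, bool)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4), bool)
        m[:2] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[3] = True, True
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap_exact_value(self):
        # |P| = |G| = 100, overlap 50 -> 2*50/200 = 0.5
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100], b[50:150] = True, True
        assert dice_coefficient(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice_coefficient(np.zeros(5, bool), np.zeros(5, bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAggregateDice:
    def test_single_slice_patient_levels_agree(self):
        p = np.zeros((1, 6, 6), bool)
        g = np.zeros((1, 6, 6), bool)
        p[0, :3], g[0, :3] = True, True
        g[0, 3] = True
        pairs = [(p, g)]
        assert aggregate_dice(pairs, "image") == aggregate_dice(pairs, "patient")

    def test_stacked_volume_dice_mixes_slices(self):
        """Slices with dice {1, 0} and equal mask sizes stack to 3-D dice 0.5."""
        g = np.zeros((2, 4, 4), bool)
        g[0, 0, :4] = True
        g[1, 0, :4] = True
        p = g.copy()
        p[1] = False
        p[1, 3, :4] = True  # same size, zero overlap on slice 2
        assert aggregate_dice([(p, g)], "patient") == 0.5
        assert aggregate_dice([(p, g)], "image") == 0.5  # mean of {1, 0}

    def test_patient_order_irrelevant(self):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(4):
            g = rng.uniform(size=(3, 5, 5)) > 0.6
            p = rng.uniform(size=(3, 5, 5)) > 0.6
            pairs.append((p, g))
        assert aggregate_dice(pairs, "patient") == pytest.approx(
            aggregate_dice(pairs[::-1], "patient"))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_dice([], "patient")


class TestMetricsFromCounts:
    def test_hand_built_counts_match_closed_forms(self):
        m = metrics_from_counts(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(5 / 6)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.75)

    def test_perfect_counts_give_unit_rates(self):
        m = metrics_from_counts(ConfusionCounts(tp=4, tn=6))
        assert all(v == 1.0 for k, v in m.items())

    def test_zero_denominators_are_undefined_not_zero(self):
        m = metrics_from_counts(ConfusionCounts(tn=7))
        assert m["specificity"] == 1.0
        assert m["sensitivity"] is None
        assert m["ppv"] is None

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        c = ConfusionCounts(tp=6, fp=2, fn=3, tn=9)
        m = metrics_from_counts(c)
        assert m["f1"] == pytest.approx(
            2 / (1 / m["ppv"] + 1 / m["sensitivity"]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestMatchAndCount:
    def _case(self, gt_cls, pred_cls, overlap=True):
        gt = _vol()
        gt[0, :4, :4] = True
        pred = _vol()
        if overlap:
            pred[0, :4, :4] = True
        else:
            pred[1, 5:8, 5:8] = True
        return ([EvalFinding(pred, pred_cls)] if pred_cls else [],
                [EvalFinding(gt, gt_cls)])

    def test_exact_predictions_have_no_errors(self):
        preds, gts = [], []
        for cls in (1, 2, 3, 4):
            p, g = self._case(cls, cls)
            preds.append(p)
            gts.append(g)
        for cutoff in CUTOFFS:
            c = match_and_count(preds, gts, cutoff, level="patient")
            assert c.fp == 0 and c.fn == 0
            assert c.total == 4

    def test_undercalled_class_is_fn_at_higher_cutoff(self):
        # GT PI-RADS 4 (class 3), predicted scope >=3 (class 2), cutoff >=4
        p, g = self._case(3, 2)
        c = match_and_count([p], [g], Cutoff("PI-RADS>=4", "ge", 3), level="patient")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 1, 0)

    def test_location_mismatch_is_fn(self):
        p, g = self._case(3, 3, overlap=False)
        c = match_and_count([p], [g], Cutoff("PI-RADS>=4", "ge", 3), level="patient")
        assert (c.tp, c.fn) == (0, 1)

    def test_alarm_on_negative_patient_is_fp(self):
        p, g = self._case(1, 4)  # GT low, predicted PI-RADS 5
        c = match_and_count([p], [g], Cutoff("PI-RADS>=4", "ge", 3), level="patient")
        assert (c.fp, c.tn) == (1, 0)

    def test_hand_built_cohort_reproduces_counts_exactly(self):
        """3 detected positives, 1 false alarm, 1 miss, 5 clean negatives."""
        preds, gts = [], []
        for _ in range(3):
            p, g = self._case(3, 3)
            preds.append(p); gts.append(g)
        p, g = self._case(1, 4)  # false alarm
        preds.append(p); gts.append(g)
        p, g = self._case(4, 1)  # miss: prediction below cutoff
        preds.append(p); gts.append(g)
        for _ in range(5):
            p, g = self._case(1, 1)
            preds.append(p); gts.append(g)
        c = match_and_count(preds, gts, Cutoff("PI-RADS>=4", "ge", 3), level="patient")
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 5)

    def test_counts_conserve_truth_totals(self):
        rng = np.random.default_rng(8)
        preds, gts = [], []
        for i in range(12):
            gt_cls = int(rng.integers(1, 5))
            pred_cls = int(rng.integers(1, 5))
            p, g = self._case(gt_cls, pred_cls, overlap=bool(rng.integers(2)))
            preds.append(p); gts.append(g)
        cutoff = Cutoff("PI-RADS>=4", "ge", 3)
        c = match_and_count(preds, gts, cutoff, level="patient")
        n_pos = sum(1 for g in gts if cutoff.test(g[0].cls))
        assert c.tp + c.fn == n_pos
        assert c.fp + c.tn == len(gts) - n_pos

    def test_image_level_counts_slices(self):
        p, g = self._case(3, 3)
        c = match_and_count([p], [g], Cutoff("PI-RADS>=4", "ge", 3), level="image")
        assert c.total == 2  # two slices
        assert c.tp == 1 and c.tn == 1


class TestBinaryAndConsistency:
    def test_binary_counts(self):
        c = binary_counts([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)

    def test_interslice_consistency_values(self):
        vol = np.zeros((4, 6, 6), bool)
        vol[0, :3, :3] = True
        vol[1, :3, :3] = True  # identical adjacent pair -> dice 1
        assert interslice_consistency(vol) == pytest.approx(0.5)  # pairs (1,1): 1, (2,3) skipped, (1,2): 0
        assert interslice_consistency(np.zeros((3, 4, 4), bool)) == 1.0
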