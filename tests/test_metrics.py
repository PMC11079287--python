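"""Confusion counting, Wald intervals, likelihood ratios, ROC/AUC."""

import math

import numpy as np
import pytest

from slidegrid import (ConfusionCounts, UndefinedMetricError,
                       grid_confusion, likelihood_ratios, metrics_table,
                       roc_auc, round_half_up, sens_spec, slide_confusion,
                       slide_outcome_from_counts, stratify, wald_interval)
from slidegrid.cohort import SlideRecord
from slidegrid.errors import ConfigError

from conftest import make_map


def pair_counting_auc(scores, truth):
    """Independent oracle: P(s+ > s-) + 0.5 P(s+ = s-) over all pairs."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos, neg = scores[truth], scores[~truth]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestGridConfusion:
    def test_identity_and_complement(self, rng):
        t = make_map(rng.random((6, 6)) < 0.4, source="truth")
        same = grid_confusion(t, t)
        assert (same.tp, same.tn) == (t.n_positive, 36 - t.n_positive)
        assert same.fp == same.fn == 0
        flipped = make_map(~t.labels)
        opp = grid_confusion(flipped, t)
        assert opp.tp == opp.tn == 0

    def test_matches_double_loop(self, rng):
        pred = make_map(rng.random((10, 10)) < 0.5)
        truth = make_map(rng.random((10, 10)) < 0.3)
        got = grid_confusion(pred, truth)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for r in range(10):
            for c in range(10):
                p, t = pred.labels[r, c], truth.labels[r, c]
                tally["tp" if p and t else "fp" if p else
                      "fn" if t else "tn"] += 1
        assert (got.tp, got.fp, got.tn, got.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"])


class TestSlideConfusion:
    def test_fp_grids_do_not_rescue_a_positive_slide(self):
        truth = make_map([[1, 0], [0, 0]], source="truth")
        pred = make_map([[0, 1], [0, 0]])  # one FP grid, zero TP grids
        cc = slide_confusion(pred, truth)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (0, 1, 0, 0)

    def test_negative_slide_outcomes(self):
        truth = make_map(np.zeros((2, 2)), source="truth")
        assert slide_confusion(make_map(np.zeros((2, 2))), truth).tn == 1
        assert slide_confusion(make_map([[0, 1], [0, 0]]), truth).fp == 1

    def test_one_tp_grid_suffices(self):
        truth = make_map([[1, 1], [0, 0]], source="truth")
        pred = make_map([[1, 0], [1, 1]])  # 1 TP grid and FP grids
        assert slide_confusion(pred, truth).tp == 1

    def test_derivation_from_stored_grid_counts(self, rng):
        """Direct slide call equals the outcome derived from grid counts."""
        key = {"TP": (1, 0, 0, 0), "FP": (0, 1, 0, 0),
               "TN": (0, 0, 1, 0), "FN": (0, 0, 0, 1)}
        for _ in range(50):
            pred = make_map(rng.random((4, 4)) < 0.3)
            truth = make_map(rng.random((4, 4)) < 0.2)
            direct = slide_confusion(pred, truth)
            derived = slide_outcome_from_counts(grid_confusion(pred, truth))
            assert (direct.tp, direct.fp, direct.tn, direct.fn) == key[derived]


class TestWaldInterval:
    def test_upper_bound_above_one_retained(self):
        m = wald_interval(163, 164)
        assert m.ci_high > 1.0
        assert m.as_percent() == (99.39, 98.20, 100.58)
        clipped = wald_interval(163, 164, clip=True)
        assert clipped.ci_high == 1.0

    def test_zero_denominator(self):
        with pytest.raises(UndefinedMetricError):
            wald_interval(0, 0)

    def test_width_shrinks_as_inverse_sqrt_n(self):
        widths = []
        for n in (100, 10_000):
            m = wald_interval(int(0.3 * n), n)
            widths.append(m.ci_high - m.ci_low)
        assert widths[0] / widths[1] == pytest.approx(10.0, rel=1e-6)

    def test_sens_spec_from_counts(self):
        cc = ConfusionCounts(tp=68_510, fn=7_404, tn=3_394_105, fp=119_457)
        sens, spec = sens_spec(cc)
        assert sens.as_percent() == (90.25, 90.04, 90.46)
        assert spec.as_percent() == (96.60, 96.58, 96.62)
        with pytest.raises(UndefinedMetricError):
            sens_spec(ConfusionCounts(tn=5, fp=5))


class TestLikelihoodRatios:
    def test_operating_point(self):
        lrs = likelihood_ratios(68_510 / 75_914, 3_394_105 / 3_513_562)
        assert round_half_up(lrs.lr_positive, 2) == 26.54
        assert round_half_up(lrs.lr_negative, 3) == 0.101

    def test_degenerate_rates(self):
        assert likelihood_ratios(0.5, 1.0).lr_positive == math.inf
        assert likelihood_ratios(1.0, 0.6783).lr_negative == 0.0
        with pytest.raises(UndefinedMetricError):
            likelihood_ratios(0.9, 0.0)
        with pytest.raises(ConfigError):
            likelihood_ratios(1.2, 0.5)


class TestRocAuc:
    def test_perfect_and_uninformative(self):
        truth = np.array([1, 1, 0, 0], dtype=bool)
        assert roc_auc([0.9, 0.8, 0.2, 0.1], truth) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], truth) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [True, True])

    def test_equals_pair_counting_with_ties(self, rng):
        for _ in range(20):
            truth = rng.random(80) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.random(80), 1)  # heavy ties
            assert roc_auc(scores, truth) == pytest.approx(
                pair_counting_auc(scores, truth), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        truth = rng.random(200) < 0.3
        scores = rng.random(200)
        base = roc_auc(scores, truth)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s ** 3):
            assert roc_auc(f(scores), truth) == pytest.approx(base, abs=1e-12)


class TestStratify:
    @staticmethod
    def _record(sid, procedure, truth, pred):
        return SlideRecord(slide_id=sid, procedure=procedure,
                           truth=make_map(truth, source="truth"),
                           prediction=make_map(pred))

    def test_procedure_split_and_overall_union(self):
        recs = [
            self._record("e1", "endoscopic", [[1, 0]], [[1, 0]]),
            self._record("e2", "endoscopic", [[0, 0]], [[0, 1]]),
            self._record("s1", "surgical", [[1, 1]], [[1, 0]]),
        ]
        by_proc = stratify(recs, "procedure")
        overall = stratify(recs, "all")["overall"]
        assert by_proc["endoscopic"]["slide"].fp == 1
        assert by_proc["surgical"]["slide"].tp == 1
        total = by_proc["endoscopic"]["grid"] + by_proc["surgical"]["grid"]
        assert (total.tp, total.fp, total.tn, total.fn) == (
            overall["grid"].tp, overall["grid"].fp,
            overall["grid"].tn, overall["grid"].fn)

    def test_area_stratum_and_empty_stratum(self):
        big = np.zeros((40, 40), dtype=bool)
        big.ravel()[:801] = True  # 50.0625 mm2 > 50
        recs = [
            self._record("a", "endoscopic", [[1, 0]], [[1, 0]]),
            SlideRecord("b", "surgical", make_map(big, source="truth"),
                        make_map(big)),
        ]
        strata = stratify(recs, "cancer_area_le_50mm2")
        assert strata["area_le_50mm2"]["slide"].total == 1
        assert strata["area_gt_50mm2"]["slide"].tp == 1
        table = metrics_table(stratify([], "all"))
        assert table.estimate.isna().all()  # empty stratum flagged undefined

    def test_unknown_key(self):
        with pytest.raises(ConfigError):
            stratify([], "patient_age")


def test_round_half_up_matches_printed_style():
    assert round_half_up(90.245, 2) == 90.25
    assert round_half_up(0.1005, 3) == 0.101
    assert round_half_up(2.675, 2) == 2.68  # decimal, not banker's/binary
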