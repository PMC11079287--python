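"""Revision classification, McNemar tests, paired performance, Venn sets."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from slidegrid import (MissSet, PairingError, ReaderAnnotationPair,
                       classify_revisions, grid_confusion, mcnemar_test,
                       missed_slides, paired_performance, venn_overlap)
from slidegrid.errors import ConfigError

from conftest import make_map


def _pair(before, after, reader="r1", slide="s1"):
    return ReaderAnnotationPair(reader_id=reader, slide_id=slide,
                                before=make_map(before),
                                after=make_map(after))


class TestClassifyRevisions:
    def test_fn_to_tp_direction(self):
        truth = make_map([[1]], source="truth")
        tab = classify_revisions(_pair([[0]], [[1]]), truth)
        assert (tab.fn_to_tp, tab.tp_to_fn, tab.fp_to_tn, tab.tn_to_fp) == \
            (1, 0, 0, 0)

    def test_unrevised_grid_not_tallied(self):
        truth = make_map([[0]], source="truth")
        tab = classify_revisions(_pair([[0]], [[0]]), truth)
        assert tab.fn_to_tp + tab.tp_to_fn + tab.fp_to_tn + tab.tn_to_fp == 0

    def test_matches_per_grid_enumeration(self, rng):
        for _ in range(5):
            t = rng.random((20, 20)) < 0.3
            b = rng.random((20, 20)) < 0.5
            a = rng.random((20, 20)) < 0.5
            tab = classify_revisions(_pair(b, a), make_map(t))
            expect = dict(fn_to_tp=0, tp_to_fn=0, fp_to_tn=0, tn_to_fp=0)
            for r, c in itertools.product(range(20), range(20)):
                before = ("TP" if b[r, c] else "FN") if t[r, c] else \
                    ("FP" if b[r, c] else "TN")
                after = ("TP" if a[r, c] else "FN") if t[r, c] else \
                    ("FP" if a[r, c] else "TN")
                if before != after:
                    expect[f"{before.lower()}_to_{after.lower()}"] += 1
            assert (tab.fn_to_tp, tab.tp_to_fn, tab.fp_to_tn, tab.tn_to_fp) \
                == (expect["fn_to_tp"], expect["tp_to_fn"],
                    expect["fp_to_tn"], expect["tn_to_fp"])

    def test_conservation_of_confusion_counts(self, rng):
        """After-counts equal before-counts shifted by the four tallies."""
        t = make_map(rng.random((15, 15)) < 0.3, source="truth")
        pair = _pair(rng.random((15, 15)) < 0.5, rng.random((15, 15)) < 0.5)
        tab = classify_revisions(pair, t)
        before = grid_confusion(pair.before, t)
        after = grid_confusion(pair.after, t)
        assert after.tp == before.tp + tab.fn_to_tp - tab.tp_to_fn
        assert after.fn == before.fn - tab.fn_to_tp + tab.tp_to_fn
        assert after.tn == before.tn + tab.fp_to_tn - tab.tn_to_fp
        assert after.fp == before.fp - tab.fp_to_tn + tab.tn_to_fp


class TestMcNemar:
    def test_large_imbalance_is_significant_under_both_variants(self):
        for variant in ("exact", "chi2_cc"):
            assert mcnemar_test(122, 2, variant).pvalue < 1e-4

    def test_balanced_discordance(self):
        assert mcnemar_test(5, 5).pvalue == pytest.approx(1.0)
        assert mcnemar_test(5, 5).method == "exact"

    def test_degenerate_no_discordance(self):
        res = mcnemar_test(0, 0)
        assert res.pvalue == 1.0 and res.degenerate

    def test_auto_variant_switch(self):
        assert mcnemar_test(10, 10).method == "exact"
        assert mcnemar_test(20, 20).method == "chi2_cc"

    @settings(derandomize=True, max_examples=60)
    @given(b=st.integers(0, 60), c=st.integers(0, 60))
    def test_two_sided_symmetry(self, b, c):
        assert mcnemar_test(b, c).pvalue == pytest.approx(
            mcnemar_test(c, b).pvalue, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            mcnemar_test(-1, 2)


class TestPairedPerformance:
    @staticmethod
    def _setup(rng, n=8):
        truths, pairs = {}, []
        for i in range(4):
            t = rng.random((6, 6)) < 0.3
            t[0, 0] = True  # every slide truth-positive or not, keep mixed
            if i % 2:
                t[:] = False
            truths[f"s{i}"] = make_map(t, source="truth")
            b = rng.random((6, 6)) < 0.4
            for reader in ("r1", "r2")[:n]:
                pairs.append(ReaderAnnotationPair(
                    reader_id=reader, slide_id=f"s{i}",
                    before=make_map(b.copy()), after=make_map(b.copy())))
        return truths, pairs

    def test_identical_readers_pool_to_the_same_estimates(self, rng):
        truths, pairs = self._setup(rng)
        frame = paired_performance(pairs, truths)
        grid = frame[(frame.granularity == "grid")
                     & (frame.metric == "sensitivity")
                     & (frame.condition == "no_ai")]
        vals = grid.set_index("reader_id").estimate
        assert vals["r1"] == vals["r2"] == vals["pooled"] == \
            vals["macro_mean"]

    def test_after_equals_before_leaves_metrics_unchanged(self, rng):
        truths, pairs = self._setup(rng)
        frame = paired_performance(pairs, truths)
        for (_, _, metric), grp in frame.groupby(
                ["reader_id", "granularity", "metric"]):
            est = grp.set_index("condition").estimate
            assert est["no_ai"] == est["with_ai"]

    def test_incomplete_pairing_detected(self, rng):
        truths, pairs = self._setup(rng)
        with pytest.raises(PairingError):
            paired_performance(pairs[:-1], truths)
        pairs[0].after = None
        with pytest.raises(PairingError):
            paired_performance(pairs, truths)


class TestMissedSlides:
    def test_definition(self):
        truths = {
            "hit": make_map([[1, 1, 0]], source="truth"),
            "miss": make_map([[1, 0, 0]], source="truth"),
            "neg": make_map([[0, 0, 0]], source="truth"),
        }
        anns = {
            "hit": make_map([[1, 0, 0]]),   # 1 of 2 positives -> not missed
            "miss": make_map([[0, 1, 0]]),  # only a negative grid -> missed
            "neg": make_map([[0, 0, 0]]),
        }
        ms = missed_slides("obs", anns, truths)
        assert ms.missed_slide_ids == frozenset({"miss"})

    def test_perfect_observer(self):
        truths = {"s": make_map([[1, 0]], source="truth")}
        assert missed_slides("obs", {"s": make_map([[1, 0]])},
                             truths).missed_slide_ids == frozenset()

    def test_requires_annotation_on_positive_slides(self):
        truths = {"s": make_map([[1]], source="truth")}
        with pytest.raises(PairingError):
            missed_slides("obs", {}, truths)


class TestVennOverlap:
    def test_pairwise_overlap_and_union(self):
        res = venn_overlap([MissSet("A", frozenset("ab")),
                            MissSet("B", frozenset("bc"))])
        assert res["intersections"]["A&B"] == 1
        assert res["exclusive"]["A"] == 1 and res["exclusive"]["A&B"] == 1
        assert res["union"] == 3

    def test_needs_two_observers(self):
        with pytest.raises(ConfigError):
            venn_overlap([MissSet("A", frozenset())])

    def test_matches_membership_enumeration(self, rng):
        universe = [f"w{i}" for i in range(26)]
        sets = {f"O{k}": frozenset(u for u in universe
                                   if rng.random() < 0.25)
                for k in range(5)}
        res = venn_overlap([MissSet(k, v) for k, v in sets.items()])
        ids = sorted(sets)
        for k in range(1, 6):
            for subset in itertools.combinations(ids, k):
                inter = sum(all(u in sets[i] for i in subset)
                            for u in universe)
                excl = sum(all(u in sets[i] for i in subset)
                           and not any(u in sets[i] for i in ids
                                       if i not in subset)
                           for u in universe)
                key = "&".join(subset)
                assert res["intersections"][key] == inter
                assert res["exclusive"][key] == excl
        assert res["union"] == sum(any(u in s for s in sets.values())
                                   for u in universe)
        # exclusive regions partition the union
        assert sum(res["exclusive"].values()) == res["union"]
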