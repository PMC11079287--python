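"""Paired with/without-AI reader analysis.

Each reader annotates every slide twice: once unaided ("no_ai") and once
while exposed to the AI's grid labels ("with_ai"). A grid whose
correctness status changes between conditions falls in exactly one of four
revision directions — FN->TP and FP->TN (beneficial), TP->FN and TN->FP
(harmful) — and the imbalance of each beneficial/harmful pair of discordant
counts is tested with McNemar's test. Per-condition performance reuses the
metrics module; the pooled "average" reader is the micro-average over
reader counts (a per-reader macro mean is also emitted). A "missed slide"
is a truth-positive slide on which an observer marked none of the
truth-positive grids; miss sets of several observers are compared by exact
Venn subset counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ConfigError, PairingError, UndefinedMetricError
from .gridding import GridLabelMap
from .metrics import (ConfusionCounts, DEFAULT_Z, grid_confusion,
                      sens_spec, slide_confusion)

CONDITIONS = ("no_ai", "with_ai")
REVISION_DIRECTIONS = ("fn_to_tp", "tp_to_fn", "fp_to_tn", "tn_to_fp")


@dataclass
class ReaderAnnotationPair:
    """One reader's before/after annotation maps for one slide."""

    reader_id: str
    slide_id: str
    before: GridLabelMap
    after: GridLabelMap | None = None
    seniority: str = "junior"

    def __post_init__(self):
        if self.after is not None:
            self.before.require_same_lattice(self.after)


@dataclass(frozen=True)
class McNemarResult:
    pvalue: float
    statistic: float | None
    method: str  # "exact" | "chi2_cc" | "degenerate"
    degenerate: bool = False


@dataclass
class RevisionTable:
    """Counts of the four revision directions for one reader (or pooled)."""

    reader_id: str
    fn_to_tp: int = 0
    tp_to_fn: int = 0
    fp_to_tn: int = 0
    tn_to_fp: int = 0
    mcnemar_positive: McNemarResult | None = None
    mcnemar_negative: McNemarResult | None = None

    def __add__(self, other: "RevisionTable") -> "RevisionTable":
        return RevisionTable(
            reader_id=self.reader_id,
            fn_to_tp=self.fn_to_tp + other.fn_to_tp,
            tp_to_fn=self.tp_to_fn + other.tp_to_fn,
            fp_to_tn=self.fp_to_tn + other.fp_to_tn,
            tn_to_fp=self.tn_to_fp + other.tn_to_fp)

    def with_pvalues(self, variant: str = "auto") -> "RevisionTable":
        return replace(
            self,
            mcnemar_positive=mcnemar_test(self.fn_to_tp, self.tp_to_fn,
                                          variant),
            mcnemar_negative=mcnemar_test(self.fp_to_tn, self.tn_to_fp,
                                          variant))


@dataclass(frozen=True)
class MissSet:
    """Truth-positive slides on which one observer marked no positive grid."""

    observer_id: str
    missed_slide_ids: frozenset


def classify_revisions(pair: ReaderAnnotationPair, truth: GridLabelMap,
                       *, with_pvalues: bool = False,
                       variant: str = "auto") -> RevisionTable:
    """Tally the four revision directions for one reader/slide pair.

    Only grids whose correctness status changed between conditions are
    tallied; each such grid falls in exactly one direction.
    """
    if pair.after is None:
        raise PairingError(f"reader {pair.reader_id} has no with-AI "
                           f"annotation for slide {pair.slide_id}")
    pair.before.require_same_lattice(truth)
    t, b, a = truth.labels, pair.before.labels, pair.after.labels
    table = RevisionTable(
        reader_id=pair.reader_id,
        fn_to_tp=int((t & ~b & a).sum()),
        tp_to_fn=int((t & b & ~a).sum()),
        fp_to_tn=int((~t & b & ~a).sum()),
        tn_to_fp=int((~t & ~b & a).sum()))
    return table.with_pvalues(variant) if with_pvalues else table


def mcnemar_test(b: int, c: int, variant: str = "auto") -> McNemarResult:
    """Two-sided McNemar test on the discordant-pair counts (b, c).

    ``variant="exact"`` uses the exact binomial sign test, ``"chi2_cc"``
    the continuity-corrected chi-square; ``"auto"`` picks exact when
    b + c < 25. The degenerate b = c = 0 case returns p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ConfigError("discordant counts must be non-negative")
    if b == 0 and c == 0:
        return McNemarResult(pvalue=1.0, statistic=None,
                             method="degenerate", degenerate=True)
    if variant == "auto":
        variant = "exact" if b + c < 25 else "chi2_cc"
    if variant == "exact":
        res = _sm_mcnemar([[0, b], [c, 0]], exact=True)
        return McNemarResult(pvalue=min(float(res.pvalue), 1.0),
                             statistic=float(res.statistic), method="exact")
    if variant == "chi2_cc":
        res = _sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True)
        return McNemarResult(pvalue=float(res.pvalue),
                             statistic=float(res.statistic), method="chi2_cc")
    raise ConfigError(f"unknown McNemar variant: {variant!r}")


def _condition_map(pair: ReaderAnnotationPair, condition: str
                   ) -> GridLabelMap:
    if condition == "no_ai":
        return pair.before
    if pair.after is None:
        raise PairingError(f"reader {pair.reader_id} slide {pair.slide_id}: "
                           f"missing with-AI annotation")
    return pair.after


def paired_performance(pairs: Iterable[ReaderAnnotationPair],
                       truths: Mapping[str, GridLabelMap],
                       z: float = DEFAULT_Z) -> pd.DataFrame:
    """Per-reader and averaged sens/spec, without vs with AI, grid and slide.

    Every reader must have both-condition annotations for every slide in
    ``truths`` (PairingError otherwise). The "pooled" pseudo-reader is the
    micro-average (summed counts); "macro_mean" is the unweighted mean of
    per-reader estimates (no interval attached).
    """
    pairs = list(pairs)
    by_reader: dict[str, dict[str, ReaderAnnotationPair]] = {}
    for p in pairs:
        by_reader.setdefault(p.reader_id, {})[p.slide_id] = p
    missing = [(rid, sid) for rid in by_reader for sid in truths
               if sid not in by_reader[rid]]
    missing += [(p.reader_id, p.slide_id) for p in pairs if p.after is None]
    if missing:
        raise PairingError(f"incomplete pairing, missing cells: "
                           f"{sorted(set(missing))[:10]}")

    counts: dict[tuple[str, str, str], ConfusionCounts] = {}
    for rid, slides in by_reader.items():
        for cond in CONDITIONS:
            grid = ConfusionCounts(granularity="grid", stratum=rid)
            slide = ConfusionCounts(granularity="slide", stratum=rid)
            for sid, truth in truths.items():
                ann = _condition_map(slides[sid], cond)
                grid = grid + grid_confusion(ann, truth)
                slide = slide + slide_confusion(ann, truth)
            counts[(rid, cond, "grid")] = grid
            counts[(rid, cond, "slide")] = slide

    rows = []

    def _emit(rid: str, cond: str, gran: str, cc: ConfusionCounts) -> None:
        try:
            sens, spec = sens_spec(cc, z)
        except UndefinedMetricError:
            return
        for metric, m in (("sensitivity", sens), ("specificity", spec)):
            rows.append({"reader_id": rid, "condition": cond,
                         "granularity": gran, "metric": metric,
                         "estimate": m.estimate, "ci_low": m.ci_low,
                         "ci_high": m.ci_high, "n": m.n})

    reader_ids = sorted(by_reader)
    for cond in CONDITIONS:
        for gran in ("grid", "slide"):
            pooled = ConfusionCounts(granularity=gran, stratum="pooled")
            for rid in reader_ids:
                cc = counts[(rid, cond, gran)]
                _emit(rid, cond, gran, cc)
                pooled = pooled + cc
            _emit("pooled", cond, gran, pooled)
    frame = pd.DataFrame(rows)
    # macro average: unweighted mean of per-reader point estimates
    per_reader = frame[frame.reader_id.isin(reader_ids)]
    macro = (per_reader.groupby(["condition", "granularity", "metric"],
                                as_index=False)
             .agg(estimate=("estimate", "mean"), n=("n", "sum")))
    macro["reader_id"] = "macro_mean"
    macro["ci_low"] = np.nan
    macro["ci_high"] = np.nan
    return pd.concat([frame, macro[frame.columns]], ignore_index=True)


def missed_slides(observer_id: str,
                  annotations: Mapping[str, GridLabelMap],
                  truths: Mapping[str, GridLabelMap]) -> MissSet:
    """Slides where the observer overlooked every truth-positive grid."""
    missed = []
    for sid, truth in truths.items():
        if not truth.labels.any():
            continue
        if sid not in annotations:
            raise PairingError(f"observer {observer_id} has no annotation "
                               f"for truth-positive slide {sid}")
        ann = annotations[sid]
        ann.require_same_lattice(truth)
        if not (ann.labels & truth.labels).any():
            missed.append(sid)
    return MissSet(observer_id=observer_id,
                   missed_slide_ids=frozenset(missed))


def venn_overlap(miss_sets: Iterable[MissSet]) -> dict:
    """Exact Venn analysis of observer miss sets.

    Returns intersection cardinalities for every non-empty observer subset
    (keys like ``"AI&JP1"``), the exclusive-region counts for the same
    subsets, per-observer totals, and the union size.
    """
    sets = {m.observer_id: set(m.missed_slide_ids) for m in miss_sets}
    if len(sets) < 2:
        raise ConfigError("Venn analysis needs at least two observers")
    ids = sorted(sets)
    union = set().union(*sets.values())
    inter: dict[str, int] = {}
    excl: dict[str, int] = {}
    for k in range(1, len(ids) + 1):
        for subset in itertools.combinations(ids, k):
            key = "&".join(subset)
            common = set.intersection(*(sets[i] for i in subset))
            inter[key] = len(common)
            others = [sets[i] for i in ids if i not in subset]
            excl[key] = len(common.difference(*others) if others else common)
    return {
        "observers": {i: len(sets[i]) for i in ids},
        "intersections": inter,
        "exclusive": excl,
        "union": len(union),
    }
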