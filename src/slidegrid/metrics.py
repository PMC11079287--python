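"""Confusion counting, Wald intervals, likelihood ratios and trapezoidal ROC.

Grid-level sensitivity is TP/(TP+FN) and specificity TN/(TN+FP) over an
exhaustive per-grid cross-tabulation against ground truth. Slide-level
counts are derived directly from grid-level results with no aggregation
model: a truth-positive slide is TP iff it has at least one TP grid
(otherwise FN, regardless of FP grids), and a truth-negative slide is TN
iff it has no positively predicted grid. Interval estimates use the Wald
normal approximation p +/- z*sqrt(p(1-p)/n) with z = 1.96, deliberately
NOT clipped to [0, 1] (a near-perfect proportion can print an upper bound
above 100%). Likelihood ratios are LR+ = sens/(1-spec) (infinite at
spec = 1) and LR- = (1-sens)/spec. The ROC curve sweeps all distinct score
thresholds and the AUC is the trapezoidal integral, which equals the
pair-counting rank statistic with 0.5 credit for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedMetricError
from .gridding import GridLabelMap

DEFAULT_Z = 1.96


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies at one granularity for one stratum."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    granularity: str = "grid"  # "grid" | "slide"
    stratum: str = "overall"

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ConfigError(f"negative count {name}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.granularity != other.granularity:
            raise ConfigError("cannot add counts across granularities")
        return replace(self, tp=self.tp + other.tp, fp=self.fp + other.fp,
                       tn=self.tn + other.tn, fn=self.fn + other.fn)

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricResult:
    """A proportion with its Wald interval (bounds not clipped to [0, 1])."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int
    z: float = DEFAULT_Z

    def as_percent(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(estimate, low, high) on the percent scale, half-up rounded."""
        return tuple(round_half_up(100 * v, ndigits)
                     for v in (self.estimate, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class LikelihoodRatios:
    lr_positive: float  # sens/(1-spec); +inf when spec == 1
    lr_negative: float  # (1-sens)/spec; 0 iff sens == 1


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report display matches printed tables)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def wald_interval(successes: int, n: int, z: float = DEFAULT_Z,
                  *, clip: bool = False, what: str = "proportion"
                  ) -> MetricResult:
    """Wald interval for a binomial proportion; errors on n == 0."""
    if n <= 0:
        raise UndefinedMetricError(f"{what} undefined: zero denominator")
    p = successes / n
    se = math.sqrt(p * (1.0 - p) / n)
    lo, hi = p - z * se, p + z * se
    if clip:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return MetricResult(estimate=p, ci_low=lo, ci_high=hi, n=n, z=z)


def sens_spec(counts: ConfusionCounts, z: float = DEFAULT_Z,
              *, clip: bool = False) -> tuple[MetricResult, MetricResult]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with Wald CIs."""
    sens = wald_interval(counts.tp, counts.n_positive, z, clip=clip,
                         what="sensitivity")
    spec = wald_interval(counts.tn, counts.n_negative, z, clip=clip,
                         what="specificity")
    return sens, spec


def likelihood_ratios(sens: float, spec: float) -> LikelihoodRatios:
    """Diagnostic likelihood ratios from a (sens, spec) operating point."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ConfigError("sens and spec must lie in [0, 1]")
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    if spec == 0.0:
        raise UndefinedMetricError("LR- undefined at specificity 0")
    lr_neg = (1.0 - sens) / spec
    return LikelihoodRatios(lr_positive=lr_pos, lr_negative=lr_neg)


def likelihood_ratios_from_counts(counts: ConfusionCounts) -> LikelihoodRatios:
    s, p = sens_spec(counts)
    return likelihood_ratios(s.estimate, p.estimate)


def grid_confusion(pred: GridLabelMap, truth: GridLabelMap,
                   stratum: str = "overall") -> ConfusionCounts:
    """Exhaustive per-grid cross-tabulation of prediction against truth."""
    pred.require_same_lattice(truth)
    p, t = pred.labels, truth.labels
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()),
        granularity="grid", stratum=stratum)


def slide_confusion(pred: GridLabelMap, truth: GridLabelMap,
                    stratum: str = "overall") -> ConfusionCounts:
    """This slide's contribution to slide-level counts.

    Positive slide (any truth-positive grid): TP iff some grid is both
    predicted and truth positive, else FN — false-positive grids do not
    rescue a positive slide. Negative slide: TN iff no grid is predicted
    positive, else FP.
    """
    pred.require_same_lattice(truth)
    p, t = pred.labels, truth.labels
    tp = fp = tn = fn = 0
    if t.any():
        if (p & t).any():
            tp = 1
        else:
            fn = 1
    else:
        if p.any():
            fp = 1
        else:
            tn = 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn,
                           granularity="slide", stratum=stratum)


def slide_outcome_from_counts(grid_counts: ConfusionCounts) -> str:
    """Slide outcome derived purely from one slide's stored grid counts."""
    if grid_counts.n_positive > 0:
        return "TP" if grid_counts.tp >= 1 else "FN"
    return "TN" if grid_counts.fp == 0 else "FP"


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Trapezoidal AUC of the ROC curve swept over all score thresholds.

    Ties are handled by simultaneous threshold crossing, equivalent to the
    rank statistic with 0.5 credit for tied positive/negative pairs.
    """
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth, dtype=bool).ravel()
    if s.shape != t.shape:
        raise ConfigError("scores and truth differ in length")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined for single-class input")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(~t_sorted)
    # keep the last index of each distinct score (simultaneous crossing)
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def roc_curve(scores: Sequence[float], truth: Sequence[bool]
              ) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) points of the threshold-swept ROC curve, origin included."""
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth, dtype=bool).ravel()
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined for single-class input")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tps, fps = np.cumsum(t_sorted), np.cumsum(~t_sorted)
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    return (np.r_[0.0, fps[last] / n_neg], np.r_[0.0, tps[last] / n_pos])


STRATIFY_KEYS = ("all", "procedure", "cancer_area_le_50mm2")


def stratify(records: Iterable, key: str = "all",
             area_cutoff_mm2: float = 50.0
             ) -> dict[str, dict[str, ConfusionCounts]]:
    """Aggregate grid- and slide-level confusion counts per stratum.

    ``key="all"`` pools everything under "overall"; ``"procedure"`` splits
    endoscopic vs surgical slides; ``"cancer_area_le_50mm2"`` splits slides
    at a ground-truth lesion area of 50 mm2 (negative slides, area 0, fall
    in the <= stratum). Empty strata yield zero counts whose metrics are
    undefined downstream.
    """
    records = list(records)
    if key == "all":
        groups = {"overall": records}
    elif key == "procedure":
        groups = {
            "endoscopic": [r for r in records if r.procedure == "endoscopic"],
            "surgical": [r for r in records if r.procedure == "surgical"],
        }
    elif key == "cancer_area_le_50mm2":
        groups = {
            "area_le_50mm2": [r for r in records
                              if r.cancer_area_mm2 <= area_cutoff_mm2],
            "area_gt_50mm2": [r for r in records
                              if r.cancer_area_mm2 > area_cutoff_mm2],
        }
    else:
        raise ConfigError(f"unknown stratification key: {key!r}")
    out: dict[str, dict[str, ConfusionCounts]] = {}
    for name, recs in groups.items():
        grid = ConfusionCounts(granularity="grid", stratum=name)
        slide = ConfusionCounts(granularity="slide", stratum=name)
        for rec in recs:
            if rec.prediction is None:
                raise ConfigError(f"slide {rec.slide_id} has no prediction")
            grid = grid + grid_confusion(rec.prediction, rec.truth, name)
            slide = slide + slide_confusion(rec.prediction, rec.truth, name)
        out[name] = {"grid": grid, "slide": slide}
    return out


def metrics_table(strata: Mapping[str, Mapping[str, ConfusionCounts]],
                  z: float = DEFAULT_Z) -> pd.DataFrame:
    """Long-form report: one row per (stratum, granularity, metric).

    Undefined metrics (empty denominators) appear with NaN estimates so
    empty strata stay visible in the report.
    """
    rows = []
    for stratum, by_gran in strata.items():
        for gran, counts in by_gran.items():
            entries: list[tuple[str, float, float, float, int]] = []
            try:
                sens, spec = sens_spec(counts, z)
                entries += [
                    ("sensitivity", sens.estimate, sens.ci_low, sens.ci_high,
                     sens.n),
                    ("specificity", spec.estimate, spec.ci_low, spec.ci_high,
                     spec.n)]
                lrs = likelihood_ratios(sens.estimate, spec.estimate)
                entries += [
                    ("lr_positive", lrs.lr_positive, math.nan, math.nan,
                     counts.total),
                    ("lr_negative", lrs.lr_negative, math.nan, math.nan,
                     counts.total)]
            except UndefinedMetricError:
                entries += [(m, math.nan, math.nan, math.nan, counts.total)
                            for m in ("sensitivity", "specificity",
                                      "lr_positive", "lr_negative")]
            for metric, est, lo, hi, n in entries:
                rows.append({"stratum": stratum, "granularity": gran,
                             "metric": metric, "estimate": est,
                             "ci_low": lo, "ci_high": hi, "n": n})
    return pd.DataFrame(rows)
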