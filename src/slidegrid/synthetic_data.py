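"""Synthetic slide cohorts, a tunable grid-level detector, and readers.

No slide images from the reference cohort are deposited anywhere, so every
pipeline stage is exercised on synthetic data generated at the grid level
(no pixel texture is synthesized). The generator's defaults emulate the
study cohort's marginals: 1,418 slides at a positive-slide prevalence of
164/1418, a surgical-procedure fraction of 238/1418, and lesions grown as
4-connected blobs whose grid-derived areas follow a log-uniform law on
[0.5, 349.25] mm2. The detection oracle stands in for the grid-level CNN
at its published operating point (sensitivity 0.9025, specificity 0.9660)
by flipping truth labels independently per grid, optionally with
Markov-coupled error clumping, and dresses its hard labels with
Beta-distributed scores so ROC machinery can be exercised. Simulated
readers draw an unaided annotation from baseline sensitivity/specificity
and then revise it with direction-specific probabilities conditional on
the AI label — the simplest generative model consistent with the
published revision-table structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import fixtures
from .cohort import SlideRecord
from .errors import ConfigError
from .gridding import (FINE_EDGE_MM, GridLabelMap, level_for_edge,
                       mesh_layout)
from .reader_study import ReaderAnnotationPair


@dataclass
class CohortConfig:
    """Cohort marginals; defaults are the study conditions."""

    n_slides: int = fixtures.TOTAL_SLIDES
    prevalence_positive_slides: float = (fixtures.POSITIVE_SLIDES
                                         / fixtures.TOTAL_SLIDES)
    surgical_fraction: float = (fixtures.SURGICAL_SLIDES
                                / fixtures.TOTAL_SLIDES)
    #: inclusive (rows, cols) ranges of the fine-grid lattice per slide
    slide_size_grids: tuple[tuple[int, int], tuple[int, int]] = (
        (80, 120), (80, 120))
    #: fixed area (float) or log-uniform support (low, high), mm2
    lesion_area_mm2: float | tuple[float, float] = \
        fixtures.LESION_AREA_MM2_RANGE
    mpp: float = 0.25
    grid_edge_mm: float = FINE_EDGE_MM
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides < 0:
            raise ConfigError("n_slides must be >= 0")
        for p, name in ((self.prevalence_positive_slides, "prevalence"),
                        (self.surgical_fraction, "surgical_fraction")):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        area = self.lesion_area_mm2
        lo = area if isinstance(area, (int, float)) else area[0]
        if lo <= 0:
            raise ConfigError("lesion area support must be positive")


@dataclass
class OracleConfig:
    """Grid-level detection oracle standing in for the trained CNN."""

    per_grid_sensitivity: float = fixtures.AI_GRID_SENSITIVITY
    per_grid_specificity: float = fixtures.AI_GRID_SPECIFICITY
    #: Markov copy probability of the error state along row-major order
    spatial_correlation: float = 0.0
    #: Beta(a, b) score laws for predicted-positive / predicted-negative
    score_beta_positive: tuple[float, float] = (8.0, 2.0)
    score_beta_negative: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        for p, name in ((self.per_grid_sensitivity, "sensitivity"),
                        (self.per_grid_specificity, "specificity")):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"per-grid {name} must lie in [0, 1]")
        if self.spatial_correlation < 0 or self.spatial_correlation >= 1:
            raise ConfigError("spatial_correlation must lie in [0, 1)")


@dataclass
class ReaderProfile:
    """Baseline rates and AI-conditional revision probabilities."""

    reader_id: str
    seniority: str = "junior"
    baseline_sensitivity: float = fixtures.READER_BASELINE_SENSITIVITY
    baseline_specificity: float = fixtures.READER_BASELINE_SPECIFICITY
    #: flip probabilities, applied only where the AI label supports the
    #: flip (e.g. fn_to_tp only on truth+/before-/AI+ grids)
    revision_probs: dict = field(default_factory=lambda: {
        "fn_to_tp": 0.0, "tp_to_fn": 0.0, "fp_to_tn": 0.0, "tn_to_fp": 0.0})
    seed: int = 0

    def validate(self) -> None:
        for p in (self.baseline_sensitivity, self.baseline_specificity,
                  *self.revision_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("reader probabilities must lie in [0, 1]")


def default_reader_profiles(oracle: OracleConfig | None = None
                            ) -> list[ReaderProfile]:
    """Four reader profiles calibrated to the published revision counts.

    Each direction probability is the published per-reader revision count,
    expressed as a rate per positive (or negative) grid of the study
    cohort, divided by the expected opportunity mass of that direction
    (e.g. FN->TP requires a before-FN grid that the AI flags).
    """
    oc = oracle or OracleConfig()
    s_r = fixtures.READER_BASELINE_SENSITIVITY
    c_r = fixtures.READER_BASELINE_SPECIFICITY
    mass = {
        "fn_to_tp": (1 - s_r) * oc.per_grid_sensitivity,
        "tp_to_fn": s_r * (1 - oc.per_grid_sensitivity),
        "fp_to_tn": (1 - c_r) * oc.per_grid_specificity,
        "tn_to_fp": c_r * (1 - oc.per_grid_specificity),
    }
    denom = {"fn_to_tp": fixtures.POSITIVE_GRIDS,
             "tp_to_fn": fixtures.POSITIVE_GRIDS,
             "fp_to_tn": fixtures.NEGATIVE_GRIDS,
             "tn_to_fp": fixtures.NEGATIVE_GRIDS}
    profiles = []
    for i, (rid, counts) in enumerate(fixtures.TABLE3.items()):
        probs = {d: min(1.0, (counts[d] / denom[d]) / mass[d])
                 for d in counts}
        profiles.append(ReaderProfile(
            reader_id=rid,
            seniority="senior" if rid == "SP" else "junior",
            revision_probs=probs, seed=i))
    return profiles


def _sample_lesion_grids(area_spec, grid_area_mm2: float, capacity: int,
                         rng: np.random.Generator) -> int:
    if isinstance(area_spec, (int, float)):
        area = float(area_spec)
    else:
        lo, hi = area_spec
        area = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    target = max(1, round(area / grid_area_mm2))
    if target > capacity:
        raise ConfigError(
            f"lesion of {area:.2f} mm2 ({target} grids) does not fit a "
            f"slide of {capacity} grids")
    return target


def _grow_lesion(n_rows: int, n_cols: int, target: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Grow a 4-connected blob of ``target`` grids by random frontier picks."""
    labels = np.zeros((n_rows, n_cols), dtype=bool)
    start = (int(rng.integers(n_rows)), int(rng.integers(n_cols)))
    region = {start}
    frontier = []

    def _push_neighbors(r: int, c: int) -> None:
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < n_rows and 0 <= cc < n_cols and (rr, cc) not in region:
                frontier.append((rr, cc))

    _push_neighbors(*start)
    while len(region) < target and frontier:
        idx = int(rng.integers(len(frontier)))
        frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
        cell = frontier.pop()
        if cell in region:
            continue
        region.add(cell)
        _push_neighbors(*cell)
    rows, cols = zip(*region)
    labels[list(rows), list(cols)] = True
    return labels


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> list[SlideRecord]:
    """Generate a cohort of slides with ground-truth grid maps.

    Positive slides receive one contiguous (4-connected) lesion whose
    grid-derived area matches the sampled lesion area within one grid;
    negative slides are all-negative. Fully deterministic under
    (config, seed).
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    (r_lo, r_hi), (c_lo, c_hi) = cfg.slide_size_grids
    grid_area = cfg.grid_edge_mm ** 2
    edge_px = cfg.grid_edge_mm * 1000.0 / cfg.mpp
    records = []
    for i in range(cfg.n_slides):
        n_rows = int(rng.integers(r_lo, r_hi + 1))
        n_cols = int(rng.integers(c_lo, c_hi + 1))
        width_px = int(round(n_cols * edge_px))
        height_px = int(round(n_rows * edge_px))
        layout = mesh_layout(width_px, height_px, cfg.mpp, cfg.grid_edge_mm)
        if layout.shape != (n_rows, n_cols):
            raise ConfigError("grid edge must be an integer pixel multiple")
        procedure = ("surgical" if rng.random() < cfg.surgical_fraction
                     else "endoscopic")
        positive = rng.random() < cfg.prevalence_positive_slides
        if positive:
            target = _sample_lesion_grids(cfg.lesion_area_mm2, grid_area,
                                          n_rows * n_cols, rng)
            labels = _grow_lesion(n_rows, n_cols, target, rng)
        else:
            labels = np.zeros((n_rows, n_cols), dtype=bool)
        truth = GridLabelMap(layout=layout, labels=labels,
                             level=level_for_edge(cfg.grid_edge_mm),
                             source="truth")
        records.append(SlideRecord(slide_id=f"S{i:04d}", procedure=procedure,
                                   truth=truth))
    return records


def simulate_oracle(truth: GridLabelMap, config: OracleConfig | None = None,
                    seed: int | None = None,
                    *, with_scores: bool = True) -> GridLabelMap:
    """Predict each grid by flipping truth with class-conditional error.

    A truth-positive grid is predicted positive with probability
    ``per_grid_sensitivity``; a truth-negative grid with probability
    ``1 - per_grid_specificity``. With ``spatial_correlation`` rho > 0 the
    error indicator is copied from the preceding grid (row-major) with
    probability rho instead of being drawn fresh, which clumps errors at
    the cost of slightly biasing marginal rates across class boundaries.
    """
    cfg = config or OracleConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t = truth.labels
    err_rate = np.where(t, 1.0 - cfg.per_grid_sensitivity,
                        1.0 - cfg.per_grid_specificity)
    if cfg.spatial_correlation > 0:
        flat_rate = err_rate.ravel()
        fresh = rng.random(flat_rate.size) < flat_rate
        copy = rng.random(flat_rate.size) < cfg.spatial_correlation
        err_flat = fresh.copy()
        for k in range(1, err_flat.size):
            if copy[k]:
                err_flat[k] = err_flat[k - 1]
        err = err_flat.reshape(t.shape)
    else:
        err = rng.random(t.shape) < err_rate
    pred = t ^ err
    scores = None
    if with_scores:
        a1, b1 = cfg.score_beta_positive
        a0, b0 = cfg.score_beta_negative
        scores = np.empty(t.shape, dtype=float)
        n_pos = int(pred.sum())
        scores[pred] = rng.beta(a1, b1, size=n_pos)
        scores[~pred] = rng.beta(a0, b0, size=pred.size - n_pos)
    return GridLabelMap(layout=truth.layout, labels=pred, level=truth.level,
                        source="ai", scores=scores)


def simulate_reader(truth: GridLabelMap, ai_pred: GridLabelMap,
                    profile: ReaderProfile, slide_id: str = "",
                    seed: int | None = None) -> ReaderAnnotationPair:
    """Draw a reader's unaided annotation and its AI-exposed revision.

    The before-map is drawn from the baseline rates; the after-map flips
    before-labels with the profile's direction-specific probabilities,
    only on grids where the AI label supports the flip.
    """
    profile.validate()
    truth.require_same_lattice(ai_pred)
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    t, ai = truth.labels, ai_pred.labels
    hit = np.where(t, profile.baseline_sensitivity,
                   1.0 - profile.baseline_specificity)
    before = rng.random(t.shape) < hit
    pr = profile.revision_probs
    u = rng.random(t.shape)
    after = before.copy()
    flip_up = ((t & ~before & ai) & (u < pr.get("fn_to_tp", 0.0))) \
        | ((~t & ~before & ai) & (u < pr.get("tn_to_fp", 0.0)))
    flip_down = ((t & before & ~ai) & (u < pr.get("tp_to_fn", 0.0))) \
        | ((~t & before & ~ai) & (u < pr.get("fp_to_tn", 0.0)))
    after[flip_up] = True
    after[flip_down] = False
    mk = lambda lab: GridLabelMap(layout=truth.layout, labels=lab,
                                  level=truth.level,
                                  source=f"reader:{profile.reader_id}")
    return ReaderAnnotationPair(reader_id=profile.reader_id,
                                slide_id=slide_id, before=mk(before),
                                after=mk(after),
                                seniority=profile.seniority)
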