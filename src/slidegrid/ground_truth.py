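"""Three-source ground-truth adjudication and slide-level truth.

Ground truth for each grid comes from two independent pathologist
annotators plus the AI output: when all three agree, the common label is
final ("consensus"); any disagreement — between the annotators, or between
either annotator and the AI — is escalated to a chief pathologist whose
label is final. The chief is modeled as a label map (or callback) queried
only on disputed grids, so by construction the chief decision cannot
depend on the sources' labels. Slide truth is aggregation-free: a slide is
positive iff at least one of its grids is positive, and its cancer area is
the positive fine-grid count times the fine-grid area (0.0625 mm2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
import pandas as pd

from .errors import AdjudicationIncompleteError, LevelError
from .gridding import FINE_EDGE_MM, GridLabelMap, LEVEL_FINE

ChiefResolver = Union[GridLabelMap, Callable[[int, int], object], None]


@dataclass(frozen=True)
class SlideTruth:
    """Slide-level ground truth derived from a grid truth map."""

    slide_id: str
    label: bool
    n_positive_grids: int
    cancer_area_mm2: float


def adjudicate(annotator_a: GridLabelMap, annotator_b: GridLabelMap,
               ai: GridLabelMap, chief: ChiefResolver = None,
               log: str = "full") -> tuple[GridLabelMap, pd.DataFrame]:
    """Adjudicate per-grid ground truth from two annotators and the AI.

    Grids where ``annotator_a == annotator_b == ai`` take that unanimous
    label; every other grid takes the chief's label. ``chief`` may be a
    GridLabelMap or a callable ``(row, col) -> label``; it is consulted
    only on disputed grids and must supply a label for each (a missing or
    None label raises AdjudicationIncompleteError).

    Returns the adjudicated truth map and an adjudication log with one row
    per grid (``log="full"``) or per disputed grid (``log="disputed"``).
    """
    annotator_a.require_same_lattice(annotator_b)
    annotator_a.require_same_lattice(ai)
    a, b, m = annotator_a.labels, annotator_b.labels, ai.labels
    consensus = (a == b) & (b == m)
    final = a.copy()
    disputed = ~consensus
    if disputed.any():
        if chief is None:
            raise AdjudicationIncompleteError(
                f"{int(disputed.sum())} disputed grids but no chief resolver")
        if isinstance(chief, GridLabelMap):
            annotator_a.require_same_lattice(chief)
            final[disputed] = chief.labels[disputed]
        else:
            rows, cols = np.nonzero(disputed)
            for r, c in zip(rows, cols):
                lab = chief(int(r), int(c))
                if lab is None:
                    raise AdjudicationIncompleteError(
                        f"chief returned no label for disputed grid "
                        f"({r}, {c})")
                final[r, c] = bool(lab)
    truth = GridLabelMap(layout=annotator_a.layout, labels=final,
                         level=annotator_a.level, source="truth")
    if log == "disputed":
        rows, cols = np.nonzero(disputed)
    else:
        rows, cols = np.nonzero(np.ones_like(consensus))
    frame = pd.DataFrame({
        "row": rows.astype(int),
        "col": cols.astype(int),
        "a": a[rows, cols],
        "b": b[rows, cols],
        "ai": m[rows, cols],
        "consensus": consensus[rows, cols],
        "final": final[rows, cols],
    })
    frame["decided_by"] = np.where(frame["consensus"], "consensus", "chief")
    return truth, frame


def slide_truth(truth: GridLabelMap, slide_id: str = "",
                *, require_fine: bool = True) -> SlideTruth:
    """Derive the slide-level truth: positive iff any grid is positive.

    The cancer area is the positive-grid count times the grid area of the
    map's level; the canonical stratification areas use the fine level
    (0.0625 mm2 per grid), so a non-fine map is rejected unless
    ``require_fine=False``.
    """
    if require_fine and truth.level != LEVEL_FINE:
        raise LevelError(
            f"slide truth areas are defined on the fine "
            f"({FINE_EDGE_MM} mm) level, got {truth.level!r}")
    n_pos = truth.n_positive
    return SlideTruth(slide_id=slide_id, label=n_pos >= 1,
                      n_positive_grids=n_pos,
                      cancer_area_mm2=n_pos * truth.layout.grid_area_mm2)
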