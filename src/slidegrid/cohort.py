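"""The per-slide record tying truth, prediction and reader maps together."""

from __future__ import annotations

from dataclasses import dataclass, field

from .gridding import GridLabelMap
from .ground_truth import SlideTruth, slide_truth

PROCEDURES = ("endoscopic", "surgical")


@dataclass
class SlideRecord:
    """One slide: identifiers, procedure type, truth and prediction maps.

    ``readers`` maps reader_id -> {"no_ai": GridLabelMap, "with_ai":
    GridLabelMap} annotation maps, when a reader study is attached.
    """

    slide_id: str
    procedure: str
    truth: GridLabelMap
    prediction: GridLabelMap | None = None
    readers: dict = field(default_factory=dict)

    def slide_truth(self, **kw) -> SlideTruth:
        return slide_truth(self.truth, self.slide_id, **kw)

    @property
    def is_positive(self) -> bool:
        return bool(self.truth.labels.any())

    @property
    def cancer_area_mm2(self) -> float:
        return self.truth.n_positive * self.truth.layout.grid_area_mm2
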