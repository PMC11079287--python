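"""Grid meshing and mask-to-grid label conversion for whole-slide rasters.

A digitized slide is reduced here to a pixel raster with a known physical
sampling resolution (MPP, microns per pixel). The slide is meshed into
disjoint square grids that jointly cover every pixel: *fine* grids of
0.25 x 0.25 mm2 are the prediction units, and *display* grids of
0.5 x 0.5 mm2 (each aggregating up to 2x2 fine grids) are the units shown
to, and annotated by, human readers. A fine grid is called positive when
the cumulative area of positive mask pixels inside it exceeds 625 um2;
display-grid labels are derived from fine labels by rollup, never assigned
independently. Positive display grids are exported as viewer annotation
boxes, colored red or yellow by whether the supporting positive region
reaches 6400 um2 (the color never enters any downstream metric).

Coordinate convention: 0-based row/column indices, origin at the slide's
top-left pixel, half-open pixel rectangles [x0, x1) x [y0, y1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _connected_components

from .errors import ConfigError, GeometryError, LevelError, ShapeMismatchError

#: physical edge of the fine (prediction) grid, mm
FINE_EDGE_MM = 0.25
#: physical edge of the display (annotation) grid, mm
DISPLAY_EDGE_MM = 0.5
#: level tags carried by GridLabelMap
LEVEL_FINE = "fine_0.25mm"
LEVEL_DISPLAY = "display_0.5mm"
#: positive-pixel area a fine grid must exceed to be labeled positive, um2
AREA_THRESHOLD_UM2 = 625.0
#: connected-region area at or above which an annotation box is red, um2
RED_BOX_AREA_UM2 = 6400.0

_EPS = 1e-9


def level_for_edge(grid_edge_mm: float) -> str:
    if math.isclose(grid_edge_mm, FINE_EDGE_MM):
        return LEVEL_FINE
    if math.isclose(grid_edge_mm, DISPLAY_EDGE_MM):
        return LEVEL_DISPLAY
    return f"custom_{grid_edge_mm:g}mm"


def edge_for_level(level: str) -> float:
    if level == LEVEL_FINE:
        return FINE_EDGE_MM
    if level == LEVEL_DISPLAY:
        return DISPLAY_EDGE_MM
    if level.startswith("custom_") and level.endswith("mm"):
        return float(level[len("custom_"):-2])
    raise LevelError(f"unknown grid level tag: {level!r}")


@dataclass(frozen=True)
class GridLayout:
    """Geometry of a full-mesh grid lattice over one slide.

    Grids are disjoint and jointly cover the slide; edge grids may be
    physically partial but are part of the mesh.
    """

    n_rows: int
    n_cols: int
    grid_edge_mm: float
    mpp: float
    slide_width_px: int
    slide_height_px: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_grids(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def grid_edge_um(self) -> float:
        return self.grid_edge_mm * 1000.0

    @property
    def grid_area_mm2(self) -> float:
        return self.grid_edge_mm ** 2

    @property
    def grid_area_um2(self) -> float:
        return self.grid_edge_um ** 2


def mesh_layout(slide_width_px: int, slide_height_px: int, mpp: float,
                grid_edge_mm: float) -> GridLayout:
    """Mesh a slide into disjoint square grids covering every pixel.

    The grid count along each axis is ``ceil(extent_px * mpp / edge_um)``,
    so the mesh always covers the full slide and edge grids may be partial.
    """
    if slide_width_px <= 0 or slide_height_px <= 0:
        raise GeometryError(
            f"slide dimensions must be positive, got "
            f"{slide_width_px} x {slide_height_px}")
    if mpp <= 0:
        raise GeometryError(f"mpp must be positive, got {mpp}")
    if grid_edge_mm <= 0:
        raise GeometryError(f"grid edge must be positive, got {grid_edge_mm}")
    edge_um = grid_edge_mm * 1000.0
    if edge_um < mpp:
        raise GeometryError(
            f"grid edge {edge_um} um is smaller than one pixel ({mpp} um)")
    n_cols = int(math.ceil(slide_width_px * mpp / edge_um - _EPS))
    n_rows = int(math.ceil(slide_height_px * mpp / edge_um - _EPS))
    return GridLayout(n_rows=n_rows, n_cols=n_cols, grid_edge_mm=grid_edge_mm,
                      mpp=mpp, slide_width_px=slide_width_px,
                      slide_height_px=slide_height_px)


def grid_edges(layout: GridLayout) -> tuple[np.ndarray, np.ndarray]:
    """Half-open pixel boundaries of the mesh along each axis.

    Returns ``(row_edges, col_edges)`` with ``len == n + 1``; grid ``(r, c)``
    owns pixels ``[row_edges[r], row_edges[r+1]) x [col_edges[c],
    col_edges[c+1])``. By construction the rectangles partition the slide.
    """
    def _edges(n: int, extent_px: int) -> np.ndarray:
        e = np.ceil(np.arange(n + 1) * layout.grid_edge_um / layout.mpp
                    - _EPS).astype(np.int64)
        e[0] = 0
        e[-1] = extent_px
        return np.minimum(e, extent_px)

    return (_edges(layout.n_rows, layout.slide_height_px),
            _edges(layout.n_cols, layout.slide_width_px))


def grid_pixel_bounds(layout: GridLayout, row: int, col: int
                      ) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle ``(x0, y0, x1, y1)`` of grid ``(row, col)``."""
    row_e, col_e = grid_edges(layout)
    return (int(col_e[col]), int(row_e[row]),
            int(col_e[col + 1]), int(row_e[row + 1]))


@dataclass
class GridLabelMap:
    """A lattice of per-grid binary labels (optionally with scores).

    The central currency of the pipeline: AI predictions, annotator labels,
    adjudicated ground truth and reader annotations are all GridLabelMaps.
    ``positive_area_um2`` carries the per-grid positive mask area when the
    map was derived from a pixel mask (used for box coloring).
    """

    layout: GridLayout
    labels: np.ndarray
    level: str
    source: str = "unknown"
    scores: np.ndarray | None = None
    positive_area_um2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.shape != self.layout.shape:
            raise ShapeMismatchError(
                f"labels shape {self.labels.shape} != layout shape "
                f"{self.layout.shape}")
        for name in ("scores", "positive_area_um2"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.layout.shape:
                    raise ShapeMismatchError(
                        f"{name} shape {arr.shape} != layout shape "
                        f"{self.layout.shape}")
                setattr(self, name, arr)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def same_lattice(self, other: "GridLabelMap") -> bool:
        return (self.layout.shape == other.layout.shape
                and self.level == other.level)

    def require_same_lattice(self, other: "GridLabelMap") -> None:
        if not self.same_lattice(other):
            raise ShapeMismatchError(
                f"grid maps differ: {self.layout.shape}/{self.level} vs "
                f"{other.layout.shape}/{other.level}")


@dataclass(frozen=True)
class AnnotationBox:
    """One viewer bounding box over a positive display grid."""

    grid_row: int
    grid_col: int
    pixel_bounds: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    color: str  # "red" | "yellow"
    region_area_um2: float


def mask_to_fine_labels(mask: np.ndarray, layout: GridLayout,
                        area_threshold_um2: float = AREA_THRESHOLD_UM2,
                        *, inclusive: bool = False,
                        source: str = "ai") -> GridLabelMap:
    """Label each grid by thresholding its cumulative positive-pixel area.

    A grid is positive iff the positive-pixel area inside it (pixel count
    times mpp^2, in um2) strictly exceeds ``area_threshold_um2``; pass
    ``inclusive=True`` for >= at the boundary. Nonzero mask values count
    as positive.
    """
    mask = np.asarray(mask)
    if mask.ndim == 3:  # RGB(A) raster: any nonzero channel
        mask = mask.any(axis=-1)
    if mask.shape != (layout.slide_height_px, layout.slide_width_px):
        raise ShapeMismatchError(
            f"mask shape {mask.shape} != slide shape "
            f"({layout.slide_height_px}, {layout.slide_width_px})")
    if area_threshold_um2 < 0:
        raise GeometryError("area threshold must be >= 0")
    binary = (mask != 0).astype(np.int64)
    row_e, col_e = grid_edges(layout)
    if np.any(np.diff(row_e) <= 0) or np.any(np.diff(col_e) <= 0):
        raise GeometryError("degenerate (zero-width) grid in mesh")
    counts = np.add.reduceat(binary, row_e[:-1], axis=0)
    counts = np.add.reduceat(counts, col_e[:-1], axis=1)
    areas = counts.astype(float) * layout.mpp ** 2
    labels = areas >= area_threshold_um2 if inclusive else areas > area_threshold_um2
    return GridLabelMap(layout=layout, labels=labels,
                        level=level_for_edge(layout.grid_edge_mm),
                        source=source, positive_area_um2=areas)


def rollup_display(fine: GridLabelMap, rule: str = "any",
                   area_threshold_um2: float = AREA_THRESHOLD_UM2
                   ) -> GridLabelMap:
    """Derive the display-level map from a fine-level map.

    Each display grid aggregates its (up to) 2x2 constituent fine grids.
    ``rule="any"`` (default) marks the display grid positive iff any
    constituent fine grid is positive; ``rule="area"`` re-applies the area
    threshold to the summed per-grid positive area (requires a map produced
    from a pixel mask).
    """
    if fine.level == LEVEL_DISPLAY:
        raise LevelError("rollup_display expects a fine-level map")
    lay = fine.layout
    disp_layout = mesh_layout(lay.slide_width_px, lay.slide_height_px,
                              lay.mpp, 2 * lay.grid_edge_mm)
    dr, dc = disp_layout.shape
    # ceil(ceil(x)/2) == ceil(x/2): the display lattice blocks the fine one.
    assert dr == math.ceil(lay.n_rows / 2) and dc == math.ceil(lay.n_cols / 2)

    def _blocks(arr: np.ndarray, fill) -> np.ndarray:
        padded = np.full((2 * dr, 2 * dc), fill, dtype=arr.dtype)
        padded[:lay.n_rows, :lay.n_cols] = arr
        return padded.reshape(dr, 2, dc, 2)

    areas = None
    if fine.positive_area_um2 is not None:
        areas = _blocks(fine.positive_area_um2, 0.0).sum(axis=(1, 3))
    if rule == "any":
        labels = _blocks(fine.labels, False).any(axis=(1, 3))
    elif rule == "area":
        if areas is None:
            raise ConfigError("rollup rule 'area' needs per-grid positive "
                              "areas (map not derived from a pixel mask)")
        labels = areas > area_threshold_um2
    else:
        raise ConfigError(f"unknown rollup rule: {rule!r}")
    scores = None
    if fine.scores is not None:
        scores = _blocks(fine.scores, -np.inf).max(axis=(1, 3))
    return GridLabelMap(layout=disp_layout, labels=labels,
                        level=level_for_edge(disp_layout.grid_edge_mm),
                        source=fine.source, scores=scores,
                        positive_area_um2=areas)


def boxes_from_labels(display: GridLabelMap, fine: GridLabelMap
                      ) -> list[AnnotationBox]:
    """One annotation box per positive display grid.

    The supporting region of a box is the union of 4-connected positive
    fine-grid components intersecting the display grid; its area (positive
    pixel area where available, otherwise full fine-grid area) decides the
    color: red iff >= 6400 um2, else yellow.
    """
    lay_f, lay_d = fine.layout, display.layout
    if (lay_f.slide_width_px, lay_f.slide_height_px) != \
            (lay_d.slide_width_px, lay_d.slide_height_px):
        raise ShapeMismatchError("display map not derived from this fine map")
    if display.level == fine.level:
        raise LevelError("need one fine and one display map")
    comp = _connected_components(fine.labels, connectivity=1)
    if fine.positive_area_um2 is not None:
        grid_area = fine.positive_area_um2
    else:
        grid_area = fine.labels * lay_f.grid_area_um2
    comp_areas = np.bincount(comp.ravel(), weights=grid_area.ravel())
    row_e, col_e = grid_edges(lay_d)
    boxes: list[AnnotationBox] = []
    for r, c in zip(*np.nonzero(display.labels)):
        block = comp[2 * r:2 * r + 2, 2 * c:2 * c + 2]
        ids = np.unique(block[block > 0])
        area = float(comp_areas[ids].sum()) if ids.size else 0.0
        color = "red" if area >= RED_BOX_AREA_UM2 else "yellow"
        boxes.append(AnnotationBox(
            grid_row=int(r), grid_col=int(c),
            pixel_bounds=(int(col_e[c]), int(row_e[r]),
                          int(col_e[c + 1]), int(row_e[r + 1])),
            color=color, region_area_um2=area))
    return boxes
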