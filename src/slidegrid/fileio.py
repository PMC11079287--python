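"""Readers and writers for the pipeline's plain-text interchange formats.

Grid label maps travel as long-form CSV (slide_id, level, row, col, label,
score) in deterministic row-major order; slide geometry lives in a YAML
manifest; annotation boxes are exported as a GeoJSON FeatureCollection in
pixel coordinates; masks come in as single-channel TIFF/PNG rasters with
nonzero meaning positive. Every writer can prepend ``# key=value`` comment
headers (used to stamp the config hash) which every reader skips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .cohort import SlideRecord
from .gridding import (AnnotationBox, GridLabelMap, GridLayout,
                       edge_for_level, mesh_layout)
from .reader_study import ReaderAnnotationPair


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask raster (PNG/TIFF); nonzero pixels are positive."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.any(axis=-1)
    return np.asarray(arr != 0)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(path: Path, frame: pd.DataFrame,
               header: Mapping[str, str] | None) -> None:
    with open(path, "w", newline="") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        frame.to_csv(fh, index=False)


def write_grid_table(path: str | Path, maps: Mapping[str, GridLabelMap],
                     header: Mapping[str, str] | None = None) -> None:
    """Write grid label maps as one long-form CSV, row-major per slide."""
    frames = []
    for sid, gmap in maps.items():
        n_rows, n_cols = gmap.layout.shape
        rows, cols = np.divmod(np.arange(gmap.layout.n_grids), n_cols)
        frame = pd.DataFrame({
            "slide_id": sid, "level": gmap.level,
            "row": rows, "col": cols,
            "label": gmap.labels.ravel().astype(int)})
        frame["score"] = (gmap.scores.ravel() if gmap.scores is not None
                          else np.nan)
        frames.append(frame)
    _write_csv(Path(path), pd.concat(frames, ignore_index=True), header)


def read_grid_table(path: str | Path, layouts: Mapping[str, GridLayout],
                    source: str = "file") -> dict[str, GridLabelMap]:
    """Read a long-form grid CSV back into dense label maps."""
    frame = pd.read_csv(path, comment="#")
    out: dict[str, GridLabelMap] = {}
    for sid, grp in frame.groupby("slide_id", sort=False):
        level = grp["level"].iloc[0]
        layout = _level_layout(layouts[str(sid)], level)
        labels = np.zeros(layout.shape, dtype=bool)
        labels[grp["row"], grp["col"]] = grp["label"].astype(bool)
        scores = None
        if grp["score"].notna().any():
            scores = np.zeros(layout.shape, dtype=float)
            scores[grp["row"], grp["col"]] = grp["score"].fillna(0.0)
        out[str(sid)] = GridLabelMap(layout=layout, labels=labels,
                                     level=level, source=source,
                                     scores=scores)
    return out


def _level_layout(base: GridLayout, level: str) -> GridLayout:
    edge = edge_for_level(level)
    return mesh_layout(base.slide_width_px, base.slide_height_px,
                       base.mpp, edge)


def write_manifest(path: str | Path, records: Iterable[SlideRecord],
                   extra: Mapping | None = None) -> None:
    slides = []
    for rec in records:
        lay = rec.truth.layout
        slides.append({"slide_id": rec.slide_id,
                       "procedure": rec.procedure,
                       "mpp": float(lay.mpp),
                       "width_px": int(lay.slide_width_px),
                       "height_px": int(lay.slide_height_px)})
    doc = {"slides": slides}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def layouts_from_manifest(manifest: Mapping, grid_edge_mm: float
                          ) -> dict[str, GridLayout]:
    out = {}
    for s in manifest["slides"]:
        out[s["slide_id"]] = mesh_layout(s["width_px"], s["height_px"],
                                         s["mpp"], grid_edge_mm)
    return out


def boxes_to_geojson(boxes: Iterable[AnnotationBox],
                     slide_id: str | None = None) -> dict:
    """Annotation boxes as a GeoJSON FeatureCollection in pixel space."""
    features = []
    for b in boxes:
        x0, y0, x1, y1 = b.pixel_bounds
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [[[x0, y0], [x1, y0], [x1, y1],
                                          [x0, y1], [x0, y0]]]},
            "properties": {"row": b.grid_row, "col": b.grid_col,
                           "color": b.color,
                           "region_area_um2": b.region_area_um2}})
    doc = {"type": "FeatureCollection", "features": features}
    if slide_id is not None:
        doc["properties"] = {"slide_id": slide_id}
    return doc


def write_boxes_geojson(path: str | Path, boxes: Iterable[AnnotationBox],
                        slide_id: str | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(boxes_to_geojson(boxes, slide_id), fh, indent=1)


def write_reader_table(path: str | Path,
                       pairs: Iterable[ReaderAnnotationPair],
                       header: Mapping[str, str] | None = None) -> None:
    """Reader annotations as sparse CSV (positive grids only).

    Columns: reader_id, condition (no_ai | with_ai), slide_id, row, col,
    label. Absent grids are negative; density is reconstructed from the
    manifest layouts on read, so the round trip is loss-free.
    """
    rows = []
    for pair in pairs:
        for cond, gmap in (("no_ai", pair.before), ("with_ai", pair.after)):
            if gmap is None:
                continue
            rr, cc = np.nonzero(gmap.labels)
            for r, c in zip(rr, cc):
                rows.append((pair.reader_id, cond, pair.slide_id,
                             int(r), int(c), 1))
    frame = pd.DataFrame(rows, columns=["reader_id", "condition", "slide_id",
                                        "row", "col", "label"])
    _write_csv(Path(path), frame, header)


def read_reader_table(path: str | Path, layouts: Mapping[str, GridLayout],
                      level: str) -> list[ReaderAnnotationPair]:
    """Rebuild dense before/after reader maps from the sparse CSV.

    Every (reader, slide) present in the layouts mapping gets a pair; a
    condition absent from the file yields an all-negative map (no_ai) or
    None (with_ai absent for every slide of that reader).
    """
    frame = pd.read_csv(path, comment="#")
    pairs: list[ReaderAnnotationPair] = []
    reader_ids = sorted(frame["reader_id"].unique())
    has_after = {rid: bool(((frame.reader_id == rid)
                            & (frame.condition == "with_ai")).any())
                 for rid in reader_ids}
    for rid in reader_ids:
        sub = frame[frame.reader_id == rid]
        for sid, base in layouts.items():
            layout = _level_layout(base, level)
            maps = {}
            for cond in ("no_ai", "with_ai"):
                pick = sub[(sub.slide_id == sid) & (sub.condition == cond)]
                labels = np.zeros(layout.shape, dtype=bool)
                labels[pick["row"], pick["col"]] = True
                maps[cond] = GridLabelMap(layout=layout, labels=labels,
                                          level=level,
                                          source=f"reader:{rid}")
            pairs.append(ReaderAnnotationPair(
                reader_id=str(rid), slide_id=sid, before=maps["no_ai"],
                after=maps["with_ai"] if has_after[rid] else None))
    return pairs


def write_json(path: str | Path, obj, header: Mapping[str, str] | None = None
               ) -> None:
    doc = dict(obj)
    if header:
        doc = {"_meta": dict(header), **doc}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
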