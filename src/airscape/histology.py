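"""Semiquantitative pathology scoring and cell-to-annotation assignment.

Each sample receives a pathology score: per-feature severity grades
0–3 (absent, mild, moderate, severe) summed over the feature vocabulary.
Scores from 5 mm cores are multiplied by 0.36 — the (3/5)² circular-area
ratio — to be comparable with 3 mm cores.  Histological annotation polygons
are drawn in image pixels and scaled by 0.2125 μm/pixel to the coordinate
space of the cell centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

UM_PER_PIXEL = 0.2125
FIVE_MM_ADJUSTMENT = 0.36  # (3 mm / 5 mm)² area ratio

# Features assessed for scoring: epithelial (alveolar + airway), vascular,
# immune and mesenchymal.  The vocabulary is configurable; this default
# carries the enumerable scored features.
DEFAULT_SCORED_FEATURES = (
    "emphysema",
    "hyperplastic alveolar epithelium",
    "bronchiolar metaplasia",
    "microscopic honeycombing",
    "muscularized artery",
    "granuloma",
    "tertiary lymphoid structure",
    "mixed inflammation",
    "fibroblastic focus",
    "severe fibrosis",
)

# Annotated feature types (drawn polygons) — a wider vocabulary than the
# scored features; "giant cell" is retained for assignment but excluded from
# differential expression because those cells fall inside granulomas.
DEFAULT_ANNOTATION_FEATURES = DEFAULT_SCORED_FEATURES + (
    "epithelial detachment",
    "remodeled epithelium",
    "interlobular septum",
    "minimally-remodeled alveoli",
    "normal alveoli",
    "remnant alveoli",
    "goblet cell metaplasia",
    "small airway",
    "artery",
    "vein",
    "venule",
    "airway smooth muscle",
    "giant cell",
    "multinucleated cell",
)
DE_EXCLUDED_ANNOTATIONS = ("giant cell",)


@dataclass
class PathologyScoreSheet:
    sample_id: str
    feature_scores: dict[str, int]
    core_diameter_mm: float = 3.0
    vocabulary: tuple[str, ...] = DEFAULT_SCORED_FEATURES


def pathology_score(sheet: PathologyScoreSheet) -> float:
    """Summed feature grades, area-adjusted (×0.36) for 5 mm cores."""
    for name, s in sheet.feature_scores.items():
        if name not in sheet.vocabulary:
            raise KeyError(f"unknown pathology feature {name!r}")
        if s not in (0, 1, 2, 3):
            raise ValueError(f"score for {name!r} must be in 0..3, got {s}")
    raw = float(sum(sheet.feature_scores.values()))
    if sheet.core_diameter_mm == 5:
        return raw * FIVE_MM_ADJUSTMENT
    return raw


@dataclass
class AnnotationPolygon:
    annotation_id: str
    feature_type: str
    vertices_px: np.ndarray  # (n, 2) in image pixels
    sample_id: str

    def to_um(self, scale_um_per_pixel: float = UM_PER_PIXEL) -> Polygon:
        poly = Polygon(np.asarray(self.vertices_px, dtype=float) * scale_um_per_pixel)
        if not poly.is_valid or len(self.vertices_px) < 3:
            raise ValueError(f"annotation {self.annotation_id!r} is not a simple polygon")
        return poly


def assign_cells_to_annotations(
    cells: pd.DataFrame,
    polygons: list[AnnotationPolygon],
    scale_um_per_pixel: float = UM_PER_PIXEL,
) -> pd.DataFrame:
    """Boolean cells × annotations membership matrix.

    A cell belongs to an annotation iff its centroid (μm) falls within the
    pixel polygon scaled by ``scale_um_per_pixel``; boundary points count as
    inside; membership in multiple annotations is allowed.  Polygons are only
    tested against cells of their own sample.
    """
    out = pd.DataFrame(
        False,
        index=pd.Index(cells["cell_id"], name="cell_id"),
        columns=[p.annotation_id for p in polygons],
    )
    xy = cells[["x_centroid", "y_centroid"]].to_numpy(dtype=float)
    samples = cells["sample_id"].to_numpy(dtype=object)
    for p in polygons:
        poly = p.to_um(scale_um_per_pixel)
        minx, miny, maxx, maxy = poly.bounds
        cand = np.flatnonzero(
            (samples == p.sample_id)
            & (xy[:, 0] >= minx)
            & (xy[:, 0] <= maxx)
            & (xy[:, 1] >= miny)
            & (xy[:, 1] <= maxy)
        )
        if cand.size:
            inside = [poly.covers(Point(*xy[i])) for i in cand]  # covers: boundary inclusive
            col = out.columns.get_loc(p.annotation_id)
            out.iloc[cand[np.asarray(inside, dtype=bool)], col] = True
    return out
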