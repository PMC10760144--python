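"""Morphological lumen (airspace) segmentation from transcript point clouds.

Transcript positions (excluding transcripts of immune-lineage cells, whose
intra-airspace accumulations would otherwise fill real lumens) are binarized
to a raster; closing/dilation/erosion denoise the tissue; an alpha shape of
the tissue pixels delineates the outer boundary; connected components of the
negative space strictly inside that boundary become lumens.  Cells within a
wall-thickness cutoff of a lumen join it (id 0 = no lumen).  A final filter
cascade isolates putatively alveolar airspaces: 25–500 member cells, nucleus
span ≥ 125 μm, k-means (k = 7) composition triage against vascular/airway
clusters, and < 20% membership in cell-based airway niches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing as binary_closing, dilation as binary_dilation, erosion as binary_erosion, disk

from .synthdata import AIRWAY_TYPES, ALVEOLAR_TYPES, IMMUNE_TYPES, NONCAP_ENDO_TYPES


@dataclass
class RasterConfig:
    pixel_size: float = 1.0  # μm / pixel
    closing_radius: int = 6
    dilation_radius: int = 2
    erosion_radius: int = 2
    margin: float = 20.0  # μm padding around the sample bounding box
    alpha: float | None = None  # 1/alpha = max triangle circumradius; None = auto
    wall_cutoff: float = 10.0  # μm, normal alveolar wall thickness
    min_lumen_area_px: int = 400
    immune_types: tuple[str, ...] = IMMUNE_TYPES

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.wall_cutoff <= 0:
            raise ValueError("pixel_size and wall_cutoff must be positive")


@dataclass
class RasterImage:
    mask: np.ndarray  # (rows, cols) bool, True where ≥1 transcript fell
    origin: tuple[float, float]  # μm coordinate of pixel (0, 0)
    pixel_size: float

    def to_pixels(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.pixel_size).astype(int)
        return row, col

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        x = self.origin[0] + (cols + 0.5) * self.pixel_size
        y = self.origin[1] + (rows + 0.5) * self.pixel_size
        return np.column_stack([x, y])


def rasterize(
    transcripts: pd.DataFrame, cells: pd.DataFrame, config: RasterConfig | None = None
) -> RasterImage:
    """Binarize non-immune transcript locations to a 2-D image.

    A pixel is True iff at least one transcript not assigned to an
    immune-lineage cell falls in it; unassigned transcripts are included.
    """
    config = config or RasterConfig()
    if len(transcripts) == 0:
        raise ValueError("no transcripts to rasterize")
    immune_cells = set(cells.loc[cells["cell_type"].isin(config.immune_types), "cell_id"])
    keep = ~transcripts["cell_id"].isin(immune_cells)
    # unassigned transcripts are still "associated with" the cell they sit on:
    # drop those whose nearest centroid is an immune cell, otherwise immune
    # accumulations inside airspaces fill the very lumens being segmented
    unassigned = transcripts["cell_id"].isna().to_numpy()
    if unassigned.any() and len(cells):
        tree = cKDTree(cells[["x_centroid", "y_centroid"]].to_numpy(float))
        pts = transcripts.loc[unassigned, ["x_location", "y_location"]].to_numpy(float)
        d, nn = tree.query(pts, distance_upper_bound=15.0)
        hit = np.isfinite(d)
        is_imm = np.zeros(len(pts), dtype=bool)
        imm_mask = cells["cell_type"].isin(config.immune_types).to_numpy()
        is_imm[hit] = imm_mask[nn[hit]]
        drop = np.zeros(len(transcripts), dtype=bool)
        drop[np.flatnonzero(unassigned)[is_imm]] = True
        keep &= ~drop
    t = transcripts.loc[keep]
    x = t["x_location"].to_numpy(float)
    y = t["y_location"].to_numpy(float)
    x0 = float(x.min()) - config.margin
    y0 = float(y.min()) - config.margin
    ncol = int(np.ceil((x.max() + config.margin - x0) / config.pixel_size)) + 1
    nrow = int(np.ceil((y.max() + config.margin - y0) / config.pixel_size)) + 1
    img = RasterImage(np.zeros((nrow, ncol), dtype=bool), (x0, y0), config.pixel_size)
    r, c = img.to_pixels(x, y)
    img.mask[r, c] = True
    return img


# --------------------------------------------------------------------------
# alpha shape
# --------------------------------------------------------------------------


def alpha_shape(points: np.ndarray, max_circumradius: float) -> shapely.Geometry:
    """Union of Delaunay triangles with circumradius below the threshold.

    The classical alpha-shape construction (alpha = 1 / max_circumradius).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
        raise ValueError("alpha shape degenerate: fewer than 4 non-collinear points")
    tri = Delaunay(pts)
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    s = (la + lb + lc) / 2.0
    area = np.sqrt(np.maximum(s * (s - la) * (s - lb) * (s - lc), 1e-30))
    circum = la * lb * lc / (4.0 * area)
    keep = circum < max_circumradius
    if not keep.any():
        raise ValueError("alpha shape empty: no triangle below the circumradius threshold")
    coords = np.stack([a[keep], b[keep], c[keep]], axis=1)
    return shapely.union_all(shapely.polygons(coords))


def _outer_boundary(geom: shapely.Geometry) -> Polygon:
    """Largest polygon of a (multi)polygon, holes removed."""
    if geom.geom_type == "Polygon":
        return Polygon(geom.exterior)
    best = max(geom.geoms, key=lambda g: g.area)
    return Polygon(best.exterior)


def _auto_circumradius(points: np.ndarray, fill_area: float) -> tuple[float, shapely.Geometry]:
    """Largest alpha (smallest circumradius cap) whose shape is a single
    polygon covering ≥ 99% of the filled tissue area; convex-hull fallback."""
    pts = np.asarray(points, dtype=float)
    span = float(max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])))
    for r in (span / 60, span / 30, span / 15, span / 8, span / 4):
        try:
            geom = alpha_shape(pts, r)
        except ValueError:
            continue
        outer = _outer_boundary(geom)
        n_parts = 1 if geom.geom_type == "Polygon" else len(geom.geoms)
        if n_parts == 1 and outer.area >= 0.99 * fill_area:
            return r, geom
    hull = shapely.convex_hull(shapely.multipoints(pts))
    return float("inf"), hull


@dataclass
class LumenSegmentation:
    labels: np.ndarray  # int image; 0 = not a lumen
    image: RasterImage
    tissue_mask: np.ndarray
    boundary: Polygon  # outer tissue boundary, μm coordinates
    areas_um2: dict[int, float] = field(default_factory=dict)

    @property
    def n_lumens(self) -> int:
        return len(self.areas_um2)


def segment_lumens(image: RasterImage, config: RasterConfig | None = None) -> LumenSegmentation:
    """Denoise the transcript raster, trace the tissue boundary by alpha
    shape, and label negative-space components strictly inside it."""
    config = config or RasterConfig()
    mask = image.mask
    tissue = binary_closing(mask, disk(config.closing_radius))
    if config.dilation_radius:
        tissue = binary_dilation(tissue, disk(config.dilation_radius))
    if config.erosion_radius:
        tissue = binary_erosion(tissue, disk(config.erosion_radius))

    rows, cols = np.nonzero(tissue)
    if len(rows) < 4:
        raise ValueError("tissue mask nearly empty; cannot trace a boundary")
    pts_px = np.column_stack([cols, rows]).astype(float)
    if len(pts_px) > 15000:  # subsample for the triangulation
        step = int(np.ceil(len(pts_px) / 15000))
        pts_px = pts_px[::step]
    filled = ndimage.binary_fill_holes(tissue)
    fill_area = float(filled.sum())
    if config.alpha is not None:
        geom = alpha_shape(pts_px, 1.0 / config.alpha)
    else:
        _, geom = _auto_circumradius(pts_px, fill_area)
    outer_px = _outer_boundary(geom)

    inside = np.zeros_like(tissue)
    ex = np.asarray(outer_px.exterior.coords)
    rr, cc = draw_polygon(ex[:, 1], ex[:, 0], shape=tissue.shape)
    inside[rr, cc] = True

    neg = inside & ~tissue
    labels, n = ndimage.label(neg)
    # relabel compactly, dropping specks
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep_ids = [i + 1 for i, a in enumerate(areas) if a >= config.min_lumen_area_px]
    out = np.zeros_like(labels)
    areas_um2 = {}
    for new_id, old in enumerate(keep_ids, start=1):
        sel = labels == old
        out[sel] = new_id
        areas_um2[new_id] = float(sel.sum()) * image.pixel_size**2

    # boundary polygon in μm coordinates
    ex_um = ex * image.pixel_size + np.asarray(image.origin)
    return LumenSegmentation(out, image, tissue, Polygon(ex_um), areas_um2)


def assign_cells_to_lumens(
    cells: pd.DataFrame, seg: LumenSegmentation, wall_cutoff: float = 10.0
) -> pd.Series:
    """Per-cell lumen id: nearest lumen pixel within ``wall_cutoff`` μm, else 0."""
    ids = np.zeros(len(cells), dtype=int)
    rows, cols = np.nonzero(seg.labels)
    if len(rows):
        centers = seg.image.pixel_centers(rows, cols)
        tree = cKDTree(centers)
        xy = cells[["x_centroid", "y_centroid"]].to_numpy(float)
        d, nn = tree.query(xy, distance_upper_bound=wall_cutoff)
        hit = np.isfinite(d) & (d <= wall_cutoff)
        ids[hit] = seg.labels[rows[nn[hit]], cols[nn[hit]]]
    return pd.Series(ids, index=pd.Index(cells["cell_id"], name="cell_id"), name="lumen_id")


# --------------------------------------------------------------------------
# lumen metrics + alveolar filtering
# --------------------------------------------------------------------------


def _max_pairwise_distance(xy: np.ndarray) -> float:
    if len(xy) < 2:
        return 0.0
    if len(xy) > 4:
        from scipy.spatial import ConvexHull

        try:
            xy = xy[ConvexHull(xy).vertices]
        except Exception:
            pass
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    return float(d.max())


def lumen_table(
    cells: pd.DataFrame,
    lumen_ids: pd.Series,
    seg: LumenSegmentation | None = None,
    type_vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Per-lumen metrics: member count, nucleus span, area, type composition."""
    c = cells.set_index("cell_id")
    c = c.join(lumen_ids)
    c = c[c["lumen_id"] > 0]
    if type_vocabulary is None:
        type_vocabulary = sorted(cells["cell_type"].unique())
    rows = []
    for lid, grp in c.groupby("lumen_id"):
        xy = grp[["x_centroid", "y_centroid"]].to_numpy(float)
        comp = grp["cell_type"].value_counts(normalize=True)
        row = {
            "lumen_id": int(lid),
            "sample_id": grp["sample_id"].iloc[0],
            "n_cells": len(grp),
            "max_nucleus_distance": _max_pairwise_distance(xy),
            "area_um2": seg.areas_um2.get(int(lid), np.nan) if seg else np.nan,
        }
        for t in type_vocabulary:
            row[f"prop:{t}"] = float(comp.get(t, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AlveolarFilterReport:
    removed_size: int = 0
    removed_span: int = 0
    removed_composition: int = 0
    removed_airway_niche: int = 0
    kept: int = 0
    composition_skipped: bool = False


def filter_alveolar(
    lumens: pd.DataFrame,
    cells: pd.DataFrame,
    lumen_ids: pd.Series,
    cell_niche: pd.Series | None = None,
    airway_niches: list[int] | None = None,
    min_cells: int = 25,
    max_cells: int = 500,
    min_span: float = 125.0,
    airway_niche_frac: float = 0.2,
    kmeans_k: int = 7,
    alveolar_floor: float | None = 0.2,
    contaminant_ceiling: float | None = 0.4,
    seed: int = 0,
    alveolar_types=ALVEOLAR_TYPES,
    airway_types=AIRWAY_TYPES,
    noncap_endo_types=NONCAP_ENDO_TYPES,
) -> tuple[pd.DataFrame, AlveolarFilterReport]:
    """Isolate putatively alveolar airspaces, in order:

    1. 25 ≤ n_cells ≤ 500 (boundaries inclusive);
    2. max pairwise nucleus distance ≥ 125 μm;
    3. k-means (k = 7) on cell-type proportions; drop clusters with a low
       mean alveolar-type proportion (< ``alveolar_floor``) AND a high mean
       airway-or-non-capillary-endothelial proportion
       (> ``contaminant_ceiling``); pass ``None`` for either threshold to
       use the across-cluster median instead (a relative variant that is
       stricter when airspaces span a severity continuum);
    4. drop lumens with ≥ 20% of member cells in cell-based airway niches.
    """
    rep = AlveolarFilterReport()
    df = lumens.copy()
    ok = (df["n_cells"] >= min_cells) & (df["n_cells"] <= max_cells)
    rep.removed_size = int((~ok).sum())
    df = df[ok]
    ok = df["max_nucleus_distance"] >= min_span
    rep.removed_span = int((~ok).sum())
    df = df[ok]

    if len(df) >= kmeans_k:
        from sklearn.cluster import KMeans

        prop_cols = [c for c in df.columns if c.startswith("prop:")]
        X = df[prop_cols].to_numpy(float)
        km = KMeans(n_clusters=kmeans_k, n_init=10, random_state=seed).fit(X)
        lab = km.labels_
        centers = pd.DataFrame(km.cluster_centers_, columns=prop_cols)
        alv = centers[[f"prop:{t}" for t in alveolar_types if f"prop:{t}" in centers]].sum(axis=1)
        bad_types = list(airway_types) + list(noncap_endo_types)
        bad = centers[[f"prop:{t}" for t in bad_types if f"prop:{t}" in centers]].sum(axis=1)
        alv_cut = alv.median() if alveolar_floor is None else alveolar_floor
        bad_cut = bad.median() if contaminant_ceiling is None else contaminant_ceiling
        drop_clusters = (alv < alv_cut) & (bad > bad_cut)
        keep_mask = ~np.isin(lab, np.flatnonzero(drop_clusters.to_numpy()))
        rep.removed_composition = int((~keep_mask).sum())
        df = df[keep_mask]
    else:
        import warnings

        warnings.warn("fewer lumens than k: composition triage skipped", stacklevel=2)
        rep.composition_skipped = True

    if cell_niche is not None and airway_niches:
        cl = cells.set_index("cell_id").join(lumen_ids).join(cell_niche.rename("cell_niche"))
        cl = cl[cl["lumen_id"] > 0]
        frac = cl.groupby("lumen_id")["cell_niche"].apply(
            lambda s: float(np.mean(np.isin(s.to_numpy(), airway_niches)))
        )
        airway_frac = df["lumen_id"].map(frac).fillna(0.0)
        ok = airway_frac < airway_niche_frac
        rep.removed_airway_niche = int((~ok).sum())
        df = df[ok]

    rep.kept = len(df)
    return df, rep
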