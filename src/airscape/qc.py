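"""Transcript/cell quality control, nuclear count matrix and dimensionality reduction.

QC mirrors standard imaging-based spatial transcriptomics practice: drop
low-confidence transcript decodes (``qv`` < 20) and blank-probe calls, build a
nuclei-restricted cell×gene count matrix, and retain cells with ≥ 12 nuclear
transcripts over ≥ 10 unique genes, ≤ 5% blank calls among high-quality
nuclear transcripts, and nucleus area within 6–80 μm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_QV_MIN = 20.0
BLANK_PREFIXES = ("BLANK", "NegControl", "Blank", "antisense", "DeprecatedCodeword")


def is_blank(features: pd.Series | np.ndarray, prefixes=BLANK_PREFIXES) -> np.ndarray:
    feats = pd.Series(np.asarray(features, dtype=object))
    mask = np.zeros(len(feats), dtype=bool)
    for p in prefixes:
        mask |= feats.str.startswith(p).to_numpy()
    return mask


def filter_transcripts(
    transcripts: pd.DataFrame, qv_min: float = DEFAULT_QV_MIN, blank_prefixes=BLANK_PREFIXES
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove low-quality (qv < qv_min) and blank-probe transcripts.

    Returns the kept records (order preserved) and removal counts by reason.
    A transcript failing both criteria is counted under ``low_qv``.
    """
    if len(transcripts) == 0:
        raise ValueError("transcripts table is empty")
    low = transcripts["qv"].to_numpy() < qv_min
    blank = is_blank(transcripts["feature_name"], blank_prefixes)
    kept = transcripts.loc[~low & ~blank]
    removed = {
        "low_qv": int(low.sum()),
        "blank": int((blank & ~low).sum()),
    }
    if len(kept) == 0:
        import warnings

        warnings.warn("all transcripts removed by QC", stacklevel=2)
    return kept, removed


@dataclass
class CellQCThresholds:
    min_transcripts: int = 12
    min_genes: int = 10
    max_blank_pct: float = 5.0
    area_range: tuple[float, float] = (6.0, 80.0)


def compute_cell_qc(
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    qv_min: float = DEFAULT_QV_MIN,
    blank_prefixes=BLANK_PREFIXES,
) -> pd.DataFrame:
    """Attach per-cell QC fields computed from high-quality nuclear transcripts.

    ``n_nuclear_transcripts`` / ``n_unique_genes`` count non-blank nuclear
    transcripts with qv ≥ qv_min; ``blank_fraction`` keeps blanks in the
    denominator (the blank criterion is meaningless after their removal).
    """
    t = transcripts
    nuclear_hq = (t["overlaps_nucleus"].astype(bool)) & (t["qv"] >= qv_min) & t["cell_id"].notna()
    sub = t.loc[nuclear_hq, ["cell_id", "feature_name"]].copy()
    blank = is_blank(sub["feature_name"], blank_prefixes)
    sub["is_blank"] = blank

    per_cell = sub.groupby("cell_id", sort=False).agg(
        n_hq=("feature_name", "size"), n_blank=("is_blank", "sum")
    )
    real = sub.loc[~blank]
    n_real = real.groupby("cell_id", sort=False).size()
    n_genes = real.groupby("cell_id", sort=False)["feature_name"].nunique()

    out = cells.copy()
    out["n_nuclear_transcripts"] = out["cell_id"].map(n_real).fillna(0).astype(int)
    out["n_unique_genes"] = out["cell_id"].map(n_genes).fillna(0).astype(int)
    n_hq = out["cell_id"].map(per_cell["n_hq"])
    n_blank = out["cell_id"].map(per_cell["n_blank"])
    with np.errstate(invalid="ignore", divide="ignore"):
        bf = (n_blank / n_hq).fillna(0.0)
    out["blank_fraction"] = bf.astype(float)
    return out


def filter_cells(
    cells: pd.DataFrame, thresholds: CellQCThresholds | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep cells passing all four QC criteria; report removals per criterion.

    A cell can be counted under several criteria (counts are per-rule, not a
    partition of removed cells).
    """
    th = thresholds or CellQCThresholds()
    for col in ("n_nuclear_transcripts", "n_unique_genes", "blank_fraction", "nucleus_area"):
        if col not in cells.columns:
            raise KeyError(f"cell table is missing required QC field {col!r}")
    c_tx = cells["n_nuclear_transcripts"] >= th.min_transcripts
    c_genes = cells["n_unique_genes"] >= th.min_genes
    c_blank = cells["blank_fraction"] * 100.0 <= th.max_blank_pct
    lo, hi = th.area_range
    c_area = (cells["nucleus_area"] >= lo) & (cells["nucleus_area"] <= hi)
    keep = c_tx & c_genes & c_blank & c_area
    report = {
        "low_transcripts": int((~c_tx).sum()),
        "low_genes": int((~c_genes).sum()),
        "high_blank": int((~c_blank).sum()),
        "area_out_of_range": int((~c_area).sum()),
        "kept": int(keep.sum()),
    }
    return cells.loc[keep], report


def build_count_matrix(
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    gene_panel: list[str] | None = None,
    qv_min: float = DEFAULT_QV_MIN,
) -> ad.AnnData:
    """Nuclei-restricted cell×gene count matrix (blank-free, qv ≥ qv_min).

    Rows follow ``cells`` order; columns are the target-gene panel (inferred
    from the data when not given).
    """
    t = transcripts
    mask = (
        t["overlaps_nucleus"].astype(bool)
        & (t["qv"] >= qv_min)
        & t["cell_id"].notna()
        & ~is_blank(t["feature_name"])
    )
    sub = t.loc[mask, ["cell_id", "feature_name"]]
    if gene_panel is None:
        gene_panel = sorted(sub["feature_name"].unique())
    cell_ids = cells["cell_id"].to_numpy(dtype=object)
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    gene_pos = {g: j for j, g in enumerate(gene_panel)}
    rows = sub["cell_id"].map(cell_pos)
    cols = sub["feature_name"].map(gene_pos)
    ok = rows.notna() & cols.notna()
    X = sp.coo_matrix(
        (
            np.ones(int(ok.sum()), dtype=np.int64),
            (rows[ok].astype(int), cols[ok].astype(int)),
        ),
        shape=(len(cell_ids), len(gene_panel)),
    ).tocsr()
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_panel, name="gene")))


def write_count_matrix(adata: ad.AnnData, outdir) -> None:
    """Write the nuclear count matrix as MTX plus per-cell and per-gene TSVs."""
    from pathlib import Path

    import scipy.io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(adata.X))
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")


def normalize_log1p(
    X: sp.spmatrix | np.ndarray, scale_to: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell depth normalization to a fixed total followed by log1p.

    ``scale_to`` defaults to the median cell total.  All-zero cells are left
    as zeros and flagged.  Returns (normalized dense matrix, zero-cell mask).
    """
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    zero = totals == 0
    if scale_to is None:
        pos = totals[~zero]
        scale_to = float(np.median(pos)) if pos.size else 1.0
    f = np.ones_like(totals)
    f[~zero] = scale_to / totals[~zero]
    return np.log1p(X * f[:, None]), zero


def select_n_pcs(
    explained_variance_ratio: np.ndarray,
    cumulative_threshold: float = 0.90,
    change_threshold: float = 0.0005,
) -> int:
    """Number of PCs: min(first PC with cumulative variance > 90%,
    last PC whose explained-variance ratio exceeds 0.05%); 1-based, ≥ 1."""
    r = np.asarray(explained_variance_ratio, dtype=float)
    if r.size < 2:
        return 1
    cum = np.cumsum(r)
    above = np.flatnonzero(cum > cumulative_threshold)
    n_cum = int(above[0]) + 1 if above.size else r.size
    big = np.flatnonzero(r > change_threshold)
    n_chg = int(big[-1]) + 1 if big.size else 1
    return max(1, min(n_cum, n_chg))


def run_pca(X_norm: np.ndarray, n_components: int = 50, seed: int = 0):
    """Centered PCA; returns (scores, explained_variance_ratio, n_selected)."""
    from sklearn.decomposition import PCA

    n_components = min(n_components, min(X_norm.shape) - 1)
    p = PCA(n_components=n_components, svd_solver="randomized", random_state=seed)
    scores = p.fit_transform(X_norm)
    n_sel = select_n_pcs(p.explained_variance_ratio_)
    return scores, p.explained_variance_ratio_, n_sel


@dataclass
class AnnotationResult:
    labels: np.ndarray
    low_confidence: np.ndarray  # all-zero (or otherwise degenerate) cells
    reference_types: list[str] = field(default_factory=list)


def annotate_cells(X_norm: np.ndarray, reference_centroids: pd.DataFrame) -> AnnotationResult:
    """Nearest-centroid cell typing by cosine distance.

    ``reference_centroids``: types × genes in the same normalized space.
    Ties break by centroid order; all-zero cells get the first type with a
    low-confidence flag.
    """
    if reference_centroids.shape[0] == 0:
        raise ValueError("reference centroid table is empty")
    C = reference_centroids.to_numpy(dtype=float)
    Cn = C / np.maximum(np.linalg.norm(C, axis=1, keepdims=True), 1e-12)
    X = np.asarray(X_norm, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms < 1e-12
    Xn = X / np.maximum(norms[:, None], 1e-12)
    sim = Xn @ Cn.T
    labels = reference_centroids.index.to_numpy(dtype=object)[np.argmax(sim, axis=1)]
    labels[zero] = reference_centroids.index[0]
    return AnnotationResult(
        labels=labels, low_confidence=zero, reference_types=list(reference_centroids.index)
    )


def reference_centroids_from_truth(
    X_norm: np.ndarray, cell_types: np.ndarray | pd.Series, genes: list[str]
) -> pd.DataFrame:
    """Mean normalized profile per true type — the synthetic stand-in for a
    curated marker reference."""
    types = pd.Series(np.asarray(cell_types, dtype=object))
    out = {}
    for t in sorted(types.unique()):
        out[t] = np.asarray(X_norm)[(types == t).to_numpy()].mean(axis=0)
    return pd.DataFrame(out, index=genes).T
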