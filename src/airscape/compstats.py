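"""Composition and pseudobulk differential statistics.

Logit-transformed proportions underpin three analyses: one-way ANOVA of
cell-type/niche composition across disease groups, linear regression of
proportions (or pseudobulk log-CPM) on continuous pathology scores, and
niche representative-gene detection with one-vs-mean-of-rest contrasts under
sample effects.  Pseudobulk differential expression across annotated
pathology features uses log₂CPM with a mean-variance precision-weight trend
(voom-style) in weighted least squares with a cell-count covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# logit proportions
# --------------------------------------------------------------------------


def logit_transform(p: np.ndarray, unit_totals: np.ndarray | float) -> np.ndarray:
    """log(p/(1−p)) after clamping p into (ε, 1−ε) with ε = 0.5/unit total."""
    p = np.asarray(p, dtype=float)
    totals = np.broadcast_to(np.asarray(unit_totals, dtype=float), p.shape)
    eps = 0.5 / totals
    pc = np.clip(p, eps, 1.0 - eps)
    return np.log(pc / (1.0 - pc))


def proportions_from_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-normalized proportions and unit totals from a units × features table."""
    totals = counts.sum(axis=1)
    return counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0), totals


# --------------------------------------------------------------------------
# group ANOVA & score regression
# --------------------------------------------------------------------------


def composition_anova(
    proportions: pd.DataFrame,
    groups: pd.Series,
    unit_totals: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of logit proportions per feature across groups.

    Features where some group has fewer than 2 units are skipped.
    """
    glabels = groups.loc[proportions.index]
    sizes = glabels.value_counts()
    if (sizes < 2).any():
        import warnings

        warnings.warn("groups with a single unit present; features skipped", stacklevel=2)
        return pd.DataFrame(columns=["F", "pvalue", "qvalue", "significant"])
    totals = unit_totals.loc[proportions.index].to_numpy()
    rows = {}
    for feat in proportions.columns:
        z = logit_transform(proportions[feat].to_numpy(), totals)
        samples = [z[(glabels == g).to_numpy()] for g in sizes.index]
        if all(np.ptp(s) == 0 for s in samples) and len(set(float(s[0]) for s in samples)) == 1:
            rows[feat] = (0.0, 1.0)
            continue
        F, p = stats.f_oneway(*samples)
        rows[feat] = (float(F), float(p))
    out = pd.DataFrame(rows, index=["F", "pvalue"]).T
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["qvalue"] < fdr
    return out


def covariate_regression(
    values: pd.DataFrame,
    scores: pd.Series,
    unit_totals: pd.Series | None = None,
    logit: bool = True,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-feature simple linear regression on a continuous covariate.

    With ``logit=True`` the units × features table is treated as proportions
    and logit-transformed (clamped by unit totals); otherwise values are used
    as-is (e.g. pseudobulk log-CPM).
    """
    x = scores.loc[values.index].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("score vector has zero variance")
    rows = {}
    for feat in values.columns:
        y = values[feat].to_numpy(float)
        if logit:
            if unit_totals is None:
                raise ValueError("logit transform needs unit totals for clamping")
            y = logit_transform(y, unit_totals.loc[values.index].to_numpy())
        res = stats.linregress(x, y)
        rows[feat] = (res.slope, res.pvalue)
    out = pd.DataFrame(rows, index=["slope", "pvalue"]).T
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["qvalue"] < fdr
    return out


# --------------------------------------------------------------------------
# niche representative genes
# --------------------------------------------------------------------------


def niche_marker_genes(
    transcripts: pd.DataFrame,
    niche_column: str = "niche",
    min_sample_fraction: float = 5e-4,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Representative genes per transcript niche.

    Per (sample, niche) gene proportions are logit-transformed; a linear
    model with sample effects estimates per-niche means, and each niche is
    contrasted against the mean of the other niches.  Samples contributing a
    proportion < ``min_sample_fraction`` of their transcripts to a niche are
    excluded from that niche's fit; niches retained in < 2 samples are
    skipped.
    """
    t = transcripts
    per_sample = t.groupby("sample_id").size()
    per_sn = t.groupby(["sample_id", niche_column]).size()
    frac = per_sn / per_sn.index.get_level_values(0).map(per_sample)
    valid = frac[frac >= min_sample_fraction].index  # (sample, niche) kept

    counts = (
        t.groupby(["sample_id", niche_column, "feature_name"]).size().rename("n").reset_index()
    )
    counts["key"] = list(zip(counts["sample_id"], counts[niche_column]))
    counts = counts[counts["key"].isin(set(valid))]
    pivot = counts.pivot_table(
        index="key", columns="feature_name", values="n", fill_value=0, aggfunc="sum"
    )
    totals = pivot.sum(axis=1)
    props = pivot.div(totals, axis=0)
    niches = pd.Series([k[1] for k in pivot.index], index=pivot.index)
    samples = pd.Series([k[0] for k in pivot.index], index=pivot.index)

    niche_support = niches.value_counts()
    keep_niches = niche_support[niche_support >= 2].index
    ok = niches.isin(keep_niches)
    props, totals, niches, samples = props[ok], totals[ok], niches[ok], samples[ok]

    # design: niche one-hot (no intercept) + sample effects (first dropped)
    niche_levels = sorted(niches.unique())
    sample_levels = sorted(samples.unique())
    Dn = np.column_stack([(niches == nl).to_numpy(float) for nl in niche_levels])
    Ds = np.column_stack([(samples == sl).to_numpy(float) for sl in sample_levels[1:]])
    X = np.column_stack([Dn, Ds]) if Ds.size else Dn
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    dof = max(len(props) - np.linalg.matrix_rank(X), 1)

    rows = []
    k = len(niche_levels)
    for gene in props.columns:
        z = logit_transform(props[gene].to_numpy(), totals.to_numpy())
        beta = H @ z
        resid = z - X @ beta
        sigma2 = float(resid @ resid) / dof
        for i, nl in enumerate(niche_levels):
            contrast = np.zeros(X.shape[1])
            contrast[:k] = -1.0 / (k - 1)
            contrast[i] = 1.0
            est = float(contrast @ beta)
            se = float(np.sqrt(sigma2 * contrast @ XtX_inv @ contrast))
            tval = est / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(tval), dof)
            rows.append({"niche": nl, "gene": gene, "estimate": est, "t": tval, "pvalue": p})
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["qvalue"] < fdr
    return out.sort_values(["niche", "pvalue"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# voom-style pseudobulk DE across pathology annotations
# --------------------------------------------------------------------------


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log₂((count + 0.5) / (library + 1) × 1e6) per unit (rows = units)."""
    lib = counts.sum(axis=1)
    return np.log2((counts + 0.5).div(lib + 1.0, axis=0) * 1e6)


def filter_expressed(
    logcpm: pd.DataFrame, threshold: float = 8.0, min_fraction: float = 0.5
) -> list[str]:
    """Genes with log₂CPM ≥ threshold in more than ``min_fraction`` of units."""
    frac = (logcpm >= threshold).mean(axis=0)
    return list(logcpm.columns[frac > min_fraction])


@dataclass
class VoomFit:
    logcpm: pd.DataFrame
    weights: pd.DataFrame
    design: np.ndarray
    design_columns: list[str]


def voom_weights(
    counts: pd.DataFrame, design: np.ndarray, span: float = 0.5
) -> VoomFit:
    """Observation-level precision weights from the mean-variance trend.

    Per-gene OLS residual standard deviations (√sd scale) are lowess-smoothed
    against mean log-count; fitted log-CPM values are mapped through the
    trend and inverted to weights — the voom construction.
    """
    logcpm = log2_cpm(counts)
    lib = counts.sum(axis=1).to_numpy(float)
    Y = logcpm.to_numpy(float)  # units × genes
    X = np.asarray(design, float)
    beta = np.linalg.pinv(X) @ Y  # coef × genes
    fitted = X @ beta  # units × genes, log-CPM scale
    resid = Y - fitted
    dof = max(len(Y) - np.linalg.matrix_rank(X), 1)
    sd = np.sqrt((resid**2).sum(axis=0) / dof)  # per gene
    shift = np.log2(lib + 1.0) - np.log2(1e6)  # log-CPM → log-count offset per unit
    mean_logcount = fitted.mean(axis=0) + shift.mean()
    lo = lowess(np.sqrt(sd), mean_logcount, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    sqrt_sd_pred = np.interp(fitted + shift[:, None], lx, ly)
    w = 1.0 / np.maximum(sqrt_sd_pred, 1e-4) ** 4
    return VoomFit(
        logcpm=logcpm,
        weights=pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns),
        design=X,
        design_columns=[f"x{i}" for i in range(X.shape[1])],
    )


def _wls_contrast(y, X, w, contrast):
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    beta = XtX_inv @ Xw.T @ yw
    resid = yw - Xw @ beta
    dof = max(len(y) - np.linalg.matrix_rank(X), 1)
    sigma2 = float(resid @ resid) / dof
    est = float(contrast @ beta)
    se = float(np.sqrt(sigma2 * contrast @ XtX_inv @ contrast))
    tval = est / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(tval), dof)
    return est, tval, p


def pseudobulk_de_annotations(
    counts: pd.DataFrame,
    annotation_types: pd.Series,
    n_cells: pd.Series,
    exclude_types: tuple[str, ...] = ("giant cell",),
    epithelial_types: tuple[str, ...] = (),
    expr_threshold: float = 8.0,
    fdr: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Differential expression across annotated pathology features.

    ``counts``: annotation instances × genes aggregated counts.  Instances of
    excluded feature types (giant cells) are dropped; annotation types with
    < 2 instances are excluded with a warning.  Each-type-vs-rest contrasts
    under a weighted linear model with annotation-type factor + cell-count
    covariate; separate pairwise epithelial-vs-epithelial contrasts.
    Returns {"one_vs_rest": ..., "epithelial": ...}.
    """
    import warnings

    ann = annotation_types.loc[counts.index]
    keep = ~ann.isin(exclude_types)
    support = ann[keep].value_counts()
    small = support[support < 2].index
    if len(small):
        warnings.warn(f"annotation types with < 2 instances excluded: {list(small)}", stacklevel=2)
    keep &= ~ann.isin(small)
    counts = counts[keep]
    ann = ann[keep]
    ncell = n_cells.loc[counts.index].to_numpy(float)

    logcpm_all = log2_cpm(counts)
    genes = filter_expressed(logcpm_all, expr_threshold)
    counts = counts[genes]

    levels = sorted(ann.unique())
    Dn = np.column_stack([(ann == lv).to_numpy(float) for lv in levels])
    covar = (ncell - ncell.mean()) / max(ncell.std(), 1e-12)
    X = np.column_stack([Dn, covar])
    vf = voom_weights(counts, X)
    Y = vf.logcpm.to_numpy(float)
    W = vf.weights.to_numpy(float)

    k = len(levels)
    rows = []
    for gi, gene in enumerate(counts.columns):
        for i, lv in enumerate(levels):
            c = np.zeros(X.shape[1])
            c[:k] = -1.0 / (k - 1)
            c[i] = 1.0
            est, tval, p = _wls_contrast(Y[:, gi], X, W[:, gi], c)
            rows.append({"annotation": lv, "gene": gene, "log2fc": est, "t": tval, "pvalue": p})
    ovr = pd.DataFrame(rows)
    ovr["qvalue"] = multipletests(ovr["pvalue"], method="fdr_bh")[1]
    ovr["significant"] = ovr["qvalue"] < fdr

    epi = pd.DataFrame(columns=["annotation_a", "annotation_b", "gene", "log2fc", "t", "pvalue"])
    epi_levels = [lv for lv in levels if lv in epithelial_types]
    if len(epi_levels) >= 2:
        rows = []
        for gi, gene in enumerate(counts.columns):
            for a in range(len(epi_levels)):
                for b in range(a + 1, len(epi_levels)):
                    c = np.zeros(X.shape[1])
                    c[levels.index(epi_levels[a])] = 1.0
                    c[levels.index(epi_levels[b])] = -1.0
                    est, tval, p = _wls_contrast(Y[:, gi], X, W[:, gi], c)
                    rows.append(
                        {
                            "annotation_a": epi_levels[a],
                            "annotation_b": epi_levels[b],
                            "gene": gene,
                            "log2fc": est,
                            "t": tval,
                            "pvalue": p,
                        }
                    )
        epi = pd.DataFrame(rows)
        epi["qvalue"] = multipletests(epi["pvalue"], method="fdr_bh")[1]
        epi["significant"] = epi["qvalue"] < fdr
    return {"one_vs_rest": ovr, "epithelial": epi}
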