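"""Association of genes, cell types and niches with airspace pseudotime.

Counts aggregated per airspace are modeled with negative-binomial generalized
additive models: log μ = s(t) + log N, with the number of aggregated cells N
as offset and s(·) a cubic regression spline with 5 knots at pseudotime
quantiles.  Association is a likelihood-ratio test of the smooth against the
intercept-only model, with Benjamini–Hochberg FDR across features.  The
cell-type-level variant adds smooths of cell-type proportions as covariates:
log μ = s(t) + Σᵢ s(pᵢ) + log N.  Peak times come from sliding-window
smoothing of the fitted curves, and fitted patterns are grouped by
hierarchical clustering of per-feature z-scored curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.signal import find_peaks
from statsmodels.stats.multitest import multipletests

DEFAULT_N_KNOTS = 5
DEFAULT_FDR = 0.01


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------


@dataclass
class LumenFeatureMatrix:
    counts: pd.DataFrame  # features × lumens, columns ordered by pseudotime
    offsets: pd.Series  # N (aggregated cells) per lumen
    pseudotime: pd.Series  # t per lumen
    mode: str  # genes | celltypes | niches

    def included_features(self, min_presence: float = 0.10) -> list[str]:
        """Features present (count > 0) in more than ``min_presence`` of lumens."""
        frac = (self.counts > 0).mean(axis=1)
        return list(self.counts.index[frac > min_presence])


def aggregate_by_lumen(
    cells: pd.DataFrame,
    lumen_ids: pd.Series,
    pseudotime: pd.Series,
    mode: str = "celltypes",
    gene_counts: pd.DataFrame | None = None,
    label_column: str | None = None,
) -> LumenFeatureMatrix:
    """Aggregate features over airspace member cells.

    ``mode='genes'`` sums nuclear gene counts of member cells (``gene_counts``:
    cells × genes indexed by cell_id); ``mode='celltypes'``/``'niches'`` count
    member cells per label (``label_column`` defaults to ``cell_type``).
    The offset N is always the member-cell count; lumens without pseudotime
    or without cells are excluded (with a warning for empty ones).
    """
    lab = label_column or ("cell_type" if mode == "celltypes" else "cell_niche")
    c = cells.set_index("cell_id").join(lumen_ids)
    c = c[c["lumen_id"].isin(pseudotime.index)]
    n_cells = c.groupby("lumen_id").size()
    empty = pseudotime.index.difference(n_cells.index)
    if len(empty):
        warnings.warn(f"{len(empty)} lumens have no member cells; excluded", stacklevel=2)
    order = pseudotime.drop(index=empty).sort_values()
    if mode == "genes":
        if gene_counts is None:
            raise ValueError("mode='genes' requires the cells × genes count table")
        g = gene_counts.join(c["lumen_id"], how="inner")
        mat = g.groupby("lumen_id").sum().T
    else:
        mat = c.pivot_table(index=lab, columns="lumen_id", aggfunc="size", fill_value=0)
    mat = mat.reindex(columns=order.index, fill_value=0)
    return LumenFeatureMatrix(
        counts=mat.astype(float),
        offsets=n_cells.reindex(order.index).astype(float),
        pseudotime=order.astype(float),
        mode=mode,
    )


# --------------------------------------------------------------------------
# spline basis & NB fitting
# --------------------------------------------------------------------------


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic regression spline basis (K knots → K−1 columns, no
    intercept column; linear beyond the boundary knots)."""
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots")

    def d(k):
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[K - 1], 0) ** 3
        return num / (knots[K - 1] - knots[k])

    dKm2 = d(K - 2)
    cols = [x] + [d(k) - dKm2 for k in range(K - 2)]
    return np.column_stack(cols)


def quantile_knots(x: np.ndarray, n_knots: int = DEFAULT_N_KNOTS) -> np.ndarray:
    """Knots at the 0/25/50/75/100% quantiles (evenly spaced quantile grid)."""
    q = np.quantile(np.asarray(x, float), np.linspace(0, 1, n_knots))
    uq = np.unique(q)
    if len(uq) < 3:  # degenerate spread: fall back to an even grid
        uq = np.linspace(float(np.min(x)), float(np.max(x)) + 1e-9, 3)
    return uq


def _standardize(B: np.ndarray) -> np.ndarray:
    B = B - B.mean(axis=0)
    sd = B.std(axis=0)
    return B / np.where(sd > 0, sd, 1.0)


def _fit_nb_glm(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    model = sm.GLM(y, X, family=fam, offset=offset)
    return model.fit(maxiter=200, tol=1e-8)


def _estimate_alpha(y, X, offset) -> float:
    """Profile-ML estimate of the NB dispersion on the full design."""
    from scipy.optimize import minimize_scalar

    def nll(log_alpha):
        try:
            res = _fit_nb_glm(y, X, offset, float(np.exp(log_alpha)))
            return -res.llf
        except Exception:
            return 1e12

    opt = minimize_scalar(nll, bounds=(np.log(1e-8), np.log(50.0)), method="bounded",
                          options={"xatol": 1e-3})
    return float(np.exp(opt.x))


@dataclass
class GamFit:
    feature: str
    pvalue: float
    statistic: float
    df: int
    dispersion: float
    fitted: np.ndarray  # μ(t)/N rate curve over lumens in pseudotime order
    converged: bool = True
    qvalue: float | None = None
    peak_time: float | None = None
    notes: list[str] = field(default_factory=list)


def fit_association_gam(
    y: np.ndarray,
    t: np.ndarray,
    N: np.ndarray,
    n_knots: int = DEFAULT_N_KNOTS,
    feature: str = "",
) -> GamFit:
    """NB-GAM of an aggregated count on s(pseudotime) with offset log N.

    The association p-value is a likelihood-ratio χ² of the smooth against
    the intercept-only NB model, with the dispersion profiled by maximum
    likelihood separately under each hypothesis."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("offsets must be positive")
    if y.sum() == 0:
        return GamFit(feature, np.nan, np.nan, 0, np.nan, np.zeros_like(t), converged=False,
                      notes=["all-zero feature"])
    offset = np.log(N)
    B = _standardize(natural_cubic_basis(t, quantile_knots(t, n_knots)))
    X_full = np.column_stack([np.ones_like(t), B])
    X_null = np.ones((len(t), 1))
    try:
        # dispersion profiled separately under each hypothesis so the LR
        # statistic compares fully maximized likelihoods
        alpha = _estimate_alpha(y, X_full, offset)
        full = _fit_nb_glm(y, X_full, offset, alpha)
        alpha0 = _estimate_alpha(y, X_null, offset)
        null = _fit_nb_glm(y, X_null, offset, alpha0)
    except Exception as exc:  # non-convergence → flagged, excluded from FDR
        return GamFit(feature, np.nan, np.nan, 0, np.nan, np.zeros_like(t), converged=False,
                      notes=[f"fit failed: {exc}"])
    lr = 2.0 * (full.llf - null.llf)
    df = X_full.shape[1] - X_null.shape[1]
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    rate = full.fittedvalues / N
    return GamFit(feature, p, float(lr), df, alpha, np.asarray(rate))


def fit_celltype_gam(
    y: np.ndarray,
    t: np.ndarray,
    proportions: pd.DataFrame,
    N: np.ndarray,
    n_knots: int = DEFAULT_N_KNOTS,
    feature: str = "",
    condition_limit: float = 1e8,
) -> GamFit:
    """Cell-type-level NB-GAM: log μ = s(t) + Σᵢ s(pᵢ) + log N.

    Tests the pseudotime smooth by likelihood ratio against the model with
    the composition smooths only.  Near-collinear composition covariates are
    dropped greedily (largest variance-inflation first) until the design is
    well conditioned."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    N = np.asarray(N, dtype=float)
    notes: list[str] = []
    if y.sum() == 0:
        return GamFit(feature, np.nan, np.nan, 0, np.nan, np.zeros_like(t), converged=False,
                      notes=["all-zero gene in focal type"])
    Bt = _standardize(natural_cubic_basis(t, quantile_knots(t, n_knots)))
    cov_blocks: dict[str, np.ndarray] = {}
    for col in proportions.columns:
        p = proportions[col].to_numpy(float)
        if np.ptp(p) <= 0:
            notes.append(f"covariate {col} constant; dropped")
            continue
        cov_blocks[col] = _standardize(natural_cubic_basis(p, quantile_knots(p, n_knots)))

    def design(blocks):
        mats = [np.ones((len(t), 1))] + list(blocks.values())
        return np.column_stack(mats)

    while cov_blocks:
        X0 = design(cov_blocks)
        if np.linalg.cond(X0.T @ X0) < condition_limit:
            break
        worst = max(
            cov_blocks,
            key=lambda c: abs(np.corrcoef(cov_blocks[c][:, 0], Bt[:, 0])[0, 1]),
        )
        notes.append(f"covariate {worst} dropped (collinearity)")
        del cov_blocks[worst]

    X_null = design(cov_blocks)
    X_full = np.column_stack([X_null, Bt])
    offset = np.log(N)
    try:
        alpha = _estimate_alpha(y, X_full, offset)
        full = _fit_nb_glm(y, X_full, offset, alpha)
        null = _fit_nb_glm(y, X_null, offset, alpha)
    except Exception as exc:
        return GamFit(feature, np.nan, np.nan, 0, np.nan, np.zeros_like(t), converged=False,
                      notes=notes + [f"fit failed: {exc}"])
    lr = 2.0 * (full.llf - null.llf)
    df = Bt.shape[1]
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return GamFit(feature, p, float(lr), df, alpha, np.asarray(full.fittedvalues / N),
                  notes=notes)


def fit_all_associations(
    mat: LumenFeatureMatrix,
    min_presence: float = 0.10,
    fdr: float = DEFAULT_FDR,
    n_knots: int = DEFAULT_N_KNOTS,
) -> pd.DataFrame:
    """Fit every included feature; BH-adjust converged fits; attach peak times."""
    t = mat.pseudotime.to_numpy()
    N = mat.offsets.to_numpy()
    feats = (
        mat.included_features(min_presence)
        if mat.mode in ("celltypes", "niches")
        else list(mat.counts.index)
    )
    fits = [
        fit_association_gam(mat.counts.loc[f].to_numpy(), t, N, n_knots=n_knots, feature=f)
        for f in feats
    ]
    ok = [f for f in fits if f.converged]
    if ok:
        q = multipletests([f.pvalue for f in ok], method="fdr_bh")[1]
        for f, qq in zip(ok, q):
            f.qvalue = float(qq)
    window = 50 if mat.mode == "genes" else 10
    window = min(window, len(t))
    for f in fits:
        if f.converged:
            f.peak_time = peak_time(f.fitted, t, window)
    rows = [
        {
            "feature": f.feature,
            "pvalue": f.pvalue,
            "qvalue": f.qvalue,
            "statistic": f.statistic,
            "dispersion": f.dispersion,
            "peak_time": f.peak_time,
            "converged": f.converged,
            "significant": (f.qvalue is not None and f.qvalue < fdr),
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["fits"] = {f.feature: f for f in fits}
    return out


# --------------------------------------------------------------------------
# peak ordering & pattern clustering
# --------------------------------------------------------------------------


def peak_time(values: np.ndarray, t: np.ndarray, window: int) -> float:
    """Pseudotime of the sliding-window (moving mean over t-ordered lumens)
    maximum of a fitted curve."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    if window > len(v):
        raise ValueError("window exceeds the number of lumens")
    kern = np.ones(window) / window
    sm_v = np.convolve(v, kern, mode="valid")
    sm_t = np.convolve(t, kern, mode="valid")
    return float(sm_t[int(np.argmax(sm_v))])


def peak_order(
    curves: pd.DataFrame, t: np.ndarray, window: int = 50
) -> pd.DataFrame:
    """Order features by ascending sliding-window peak time (ties by id)."""
    window = int(window)
    peaks = {f: peak_time(curves.loc[f].to_numpy(), t, window) for f in curves.index}
    out = pd.DataFrame({"feature": list(peaks), "peak_time": list(peaks.values())})
    return out.sort_values(["peak_time", "feature"], kind="stable").reset_index(drop=True)


def cluster_patterns(
    curves: pd.DataFrame,
    k: int = 14,
    prominence: float = 0.25,
) -> pd.DataFrame:
    """Group fitted expression patterns and flag their modality.

    Per-feature curves (on a common pseudotime grid) are z-scored and
    clustered (agglomerative, Euclidean, Ward, cut at ``k``).  Modality is
    the count of interior local maxima of the z-scored curve above the given
    prominence: 1 → unimodal, 2 → bimodal, otherwise neither.
    """
    from sklearn.cluster import AgglomerativeClustering

    if k > len(curves):
        raise ValueError("k exceeds the number of features")
    X = curves.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(Z) + 1
    modality = []
    for z in Z:
        pk, _ = find_peaks(z, prominence=prominence)
        interior = [i for i in pk if 0 < i < len(z) - 1]
        n = len(interior)
        modality.append("unimodal" if n == 1 else "bimodal" if n == 2 else "other")
    return pd.DataFrame(
        {"pattern_cluster": labels, "modality": modality}, index=curves.index
    )
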