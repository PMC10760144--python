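"""Pseudotime ranking of airspaces from homeostatic to remodeled.

Composition-space trajectory in the style of slingshot: PCA on per-airspace
cell-type proportions (first three PCs), Gaussian-mixture clustering (k = 5),
minimum spanning tree over the cluster centroids, smoothing of the
start-rooted MST path by iterated principal-curve fitting, and projection of
every airspace onto the smooth curve.  Pseudotime t is the arc length of the
projection; the origin is the cluster most normal in composition (maximal
mean alveolar-type proportion by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .synthdata import ALVEOLAR_TYPES

HOMEOSTATIC_TYPES = ("AT1", "AT2", "Capillary", "Alveolar fibroblast")


def composition_pca(
    compositions: pd.DataFrame, n_pcs: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA on cell-type proportion vectors; first ``n_pcs`` scores.

    Accepts raw counts too (rows are renormalized to proportions first).
    Returns (scores, explained_variance_ratio).
    """
    X = compositions.to_numpy(dtype=float)
    if len(X) < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 airspaces")
    totals = X.sum(axis=1, keepdims=True)
    if not np.allclose(totals, 1.0, atol=1e-6):
        X = X / np.maximum(totals, 1e-12)
    if float(np.var(X, axis=0).sum()) < 1e-12:
        raise ValueError("compositions are constant: zero variance for PCA")
    p = PCA(n_components=n_pcs)
    scores = p.fit_transform(X)
    return scores, p.explained_variance_ratio_


@dataclass
class TrajectoryFit:
    scores: np.ndarray
    cluster_labels: np.ndarray
    centroids: np.ndarray
    mst_edges: list[tuple[int, int]]
    path_order: list[int]
    curve: np.ndarray  # ordered control points on the smooth curve
    pseudotime: np.ndarray
    start_cluster: int
    converged: bool = True
    n_iterations: int = 0
    notes: list[str] = field(default_factory=list)


def _mst_path_from(centroids: np.ndarray, start: int) -> tuple[list[tuple[int, int]], list[int], bool]:
    """MST over centroids (Euclidean) and the longest weighted simple path
    rooted at the start cluster (the trajectory backbone)."""
    D = cdist(centroids, centroids)
    mst = minimum_spanning_tree(D).toarray()
    k = len(centroids)
    adj: dict[int, list[int]] = {i: [] for i in range(k)}
    edges = []
    for i in range(k):
        for j in range(k):
            if mst[i, j] > 0:
                adj[i].append(j)
                adj[j].append(i)
                edges.append((i, j))

    best: list[int] = [start]

    def dfs(node, seen, path, length):
        nonlocal best, best_len
        if length > best_len:
            best, best_len = list(path), length
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                path.append(nb)
                dfs(nb, seen, path, length + D[node, nb])
                path.pop()
                seen.remove(nb)

    best_len = -1.0
    dfs(start, {start}, [start], 0.0)  # longest weighted start-rooted path
    path = best
    branching = len(path) < k
    return edges, path, branching


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; returns (arc length t, squared dist)."""
    seg_a = curve[:-1]
    seg_b = curve[1:]
    seg_v = seg_b - seg_a
    seg_len = np.linalg.norm(seg_v, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = np.empty(len(points))
    d2 = np.full(len(points), np.inf)
    for s in range(len(seg_a)):
        v = seg_v[s]
        L2 = max(seg_len[s] ** 2, 1e-24)
        u = np.clip(((points - seg_a[s]) @ v) / L2, 0.0, 1.0)
        proj = seg_a[s] + u[:, None] * v
        dd = np.sum((points - proj) ** 2, axis=1)
        better = dd < d2
        d2[better] = dd[better]
        t[better] = cum[s] + u[better] * seg_len[s]
    return t, d2


def _smooth_curve(points: np.ndarray, t: np.ndarray, n_ctrl: int = 50):
    """Re-fit the curve by local averaging: points are ordered by their
    current projection parameter, grouped into quantile bins, and each bin's
    coordinate mean becomes a control point (lightly smoothed along the
    curve) — the classical projection/conditional-expectation iteration of
    principal-curve fitting."""
    order = np.argsort(t, kind="stable")
    n_ctrl = int(min(n_ctrl, max(len(t) // 5, 2)))
    bins = np.array_split(order, n_ctrl)
    ctrl = np.vstack([points[b].mean(axis=0) for b in bins if len(b)])
    if len(ctrl) >= 3:  # 3-point moving average, endpoints kept
        inner = (ctrl[:-2] + ctrl[1:-1] + ctrl[2:]) / 3.0
        ctrl = np.vstack([ctrl[0], inner, ctrl[-1]])
    return ctrl


def _extend_tips(curve: np.ndarray, frac: float = 0.25) -> np.ndarray:
    """Prolong both terminal segments so extreme points project onto curve
    interior instead of piling up (tied) at the terminal control points.
    Applied once after convergence; extending during the iterations would let
    noisy tip directions attract off-curve points."""
    if len(curve) < 2:
        return curve
    total = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()
    out = curve
    for end, other in ((0, 1), (-1, -2)):
        v = out[end] - out[other]
        norm = np.linalg.norm(v)
        if norm > 0:
            ext = out[end] + v / norm * frac * total
            out = np.vstack([ext, out]) if end == 0 else np.vstack([out, ext])
    return out


def fit_pseudotime(
    scores: np.ndarray,
    compositions: pd.DataFrame | None = None,
    gmm_k: int = 5,
    seed: int = 0,
    start_rule: str | int = "homeostatic",
    homeostatic_types=HOMEOSTATIC_TYPES,
    max_iter: int = 10,
    tol: float = 1e-6,
    normalize: bool = False,
) -> TrajectoryFit:
    """Principal-curve pseudotime over composition-space scores.

    ``start_rule``: ``"homeostatic"`` picks the cluster with maximal mean
    alveolar-type proportion (requires ``compositions``); an integer names a
    start cluster directly.  ``normalize`` rescales t to [0, 1]; the default
    keeps arc-length units.
    """
    scores = np.asarray(scores, dtype=float)
    gmm = GaussianMixture(
        n_components=gmm_k, covariance_type="full", random_state=seed,
        init_params="k-means++", tol=1e-4, reg_covar=1e-6,
    )
    labels = gmm.fit_predict(scores)
    centroids = np.vstack([scores[labels == i].mean(axis=0) for i in range(gmm_k)])

    notes: list[str] = []
    if isinstance(start_rule, (int, np.integer)):
        start = int(start_rule)
    elif start_rule == "homeostatic":
        if compositions is None:
            raise ValueError("start_rule 'homeostatic' needs the composition table")
        cols = [c for c in compositions.columns if c.replace("prop:", "") in homeostatic_types]
        if not cols:
            cols = [c for c in compositions.columns if c.replace("prop:", "") in ALVEOLAR_TYPES]
        alv = compositions[cols].sum(axis=1).to_numpy(float)
        start = int(np.argmax([alv[labels == i].mean() for i in range(gmm_k)]))
    else:
        raise ValueError(f"unknown start_rule {start_rule!r}")

    edges, path, branching = _mst_path_from(centroids, start)
    if branching:
        notes.append("MST branches: clusters off the diameter path are handled by projection")
        warnings.warn(notes[-1], stacklevel=2)

    curve = centroids[path]
    # densify the initial polyline before smoothing
    t, _ = _project_to_polyline(scores, curve)
    prev_t = t
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        curve = _smooth_curve(scores, prev_t)
        t, _ = _project_to_polyline(scores, curve)
        delta = float(np.mean(np.abs(t - prev_t))) / max(float(t.max()), 1e-12)
        prev_t = t
        if delta < tol:
            converged = True
            break
    t, _ = _project_to_polyline(scores, _extend_tips(curve))
    if normalize and t.max() > 0:
        t = t / t.max()
    return TrajectoryFit(
        scores=scores,
        cluster_labels=labels,
        centroids=centroids,
        mst_edges=edges,
        path_order=path,
        curve=curve,
        pseudotime=t,
        start_cluster=start,
        converged=converged,
        n_iterations=it,
        notes=notes,
    )
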