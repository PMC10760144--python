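"""Cell-agnostic transcript niches.

Pipeline: per-sample spatial transcript graph (edges between transcripts
closer than d = 3.0 μm, small components dropped) → unsupervised 2-hop
mean-aggregator graph embedding (GraphSAGE-style, trained by link prediction
with negative sampling) → Gaussian-mixture clustering (k = 12) of the pooled
embeddings → hexagonal-bin majority maps → nearest-bin cell assignment.

The embedding consumes only transcript positions and gene identities; cell
assignments never enter, which is what makes the niches cell-agnostic.  The
network is a two-layer mean aggregator over one-hot gene features, trained
with plain Adam SGD in numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

DEFAULT_D = 3.0
DEFAULT_MIN_COMPONENT = 10


# --------------------------------------------------------------------------
# graph construction
# --------------------------------------------------------------------------


@dataclass
class TranscriptGraph:
    sample_id: str
    xy: np.ndarray  # (n, 2) μm
    gene_idx: np.ndarray  # (n,) into the shared gene vocabulary
    adj: sp.csr_matrix  # symmetric, no self loops
    source_rows: np.ndarray  # rows of the input transcript table that survived

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adj.nnz // 2)


def build_graph(
    transcripts: pd.DataFrame,
    gene_vocabulary: list[str],
    d: float = DEFAULT_D,
    min_component: int = DEFAULT_MIN_COMPONENT,
) -> TranscriptGraph:
    """Spatial graph of one sample's QC-passed transcripts.

    Edges connect pairs at Euclidean distance strictly below ``d``; connected
    components with fewer than ``min_component`` nodes are removed.
    """
    sample_ids = transcripts["sample_id"].unique()
    if len(sample_ids) > 1:
        raise ValueError("build_graph expects transcripts of a single sample")
    sample_id = str(sample_ids[0]) if len(sample_ids) else ""
    xy = transcripts[["x_location", "y_location"]].to_numpy(dtype=float)
    gpos = {g: i for i, g in enumerate(gene_vocabulary)}
    gene_idx = transcripts["feature_name"].map(gpos)
    if gene_idx.isna().any():
        raise ValueError("transcripts contain genes outside the vocabulary (blanks not removed?)")
    gene_idx = gene_idx.to_numpy(dtype=np.int64)
    n = len(xy)
    if n == 0:
        return TranscriptGraph(
            sample_id, xy, gene_idx, sp.csr_matrix((0, 0)), np.empty(0, dtype=int)
        )
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=d, output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[dist < d]  # strict inequality
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, dtype=int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, dtype=int)
    adj = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    keep = np.flatnonzero(sizes[labels] >= min_component)
    remap = -np.ones(n, dtype=int)
    remap[keep] = np.arange(len(keep))
    adj = adj[keep][:, keep].tocsr()
    idx = transcripts.index.to_numpy()
    return TranscriptGraph(sample_id, xy[keep], gene_idx[keep], adj, idx[keep])


# --------------------------------------------------------------------------
# embedding model
# --------------------------------------------------------------------------


@dataclass
class EmbeddingModel:
    """Two-hop mean-aggregating node embedding trained by link prediction."""

    n_genes: int
    hops: int = 2
    fanout: tuple[int, int] = (20, 10)
    hidden_dim: int = 50
    out_dim: int = 50
    epochs: int = 10
    roots_per_sample: int = 5000
    negatives_per_edge: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 512
    pairs_per_epoch: int | None = None  # default: one pass over sampled edges
    seed: int = 0
    params: dict = field(default_factory=dict)
    loss_trace: list = field(default_factory=list)
    train_accuracy: float | None = None

    def __post_init__(self) -> None:
        if len(self.fanout) != self.hops:
            raise ValueError("fanout length must equal number of hops")
        if not self.params:
            rng = np.random.default_rng(self.seed)
            G, H, D = self.n_genes, self.hidden_dim, self.out_dim

            def init(a, b):
                return (rng.standard_normal((a, b)) * math.sqrt(2.0 / (a + b))).astype(np.float32)

            self.params = {
                "W1s": init(G, H),
                "W1n": init(G, H),
                "b1": np.zeros(H, dtype=np.float32),
                "W2s": init(H, D),
                "W2n": init(H, D),
                "b2": np.zeros(D, dtype=np.float32),
            }


@dataclass
class _MergedGraph:
    gene_idx: np.ndarray
    adj: sp.csr_matrix
    node_sample: np.ndarray  # graph index per node
    node_local: np.ndarray  # node index within its source graph


def merge_graphs(graphs: list[TranscriptGraph]) -> _MergedGraph:
    """Disjoint union of per-sample graphs."""
    gene_idx = np.concatenate([g.gene_idx for g in graphs])
    adj = sp.block_diag([g.adj for g in graphs], format="csr")
    node_sample = np.concatenate([np.full(g.n_nodes, i) for i, g in enumerate(graphs)])
    node_local = np.concatenate([np.arange(g.n_nodes) for g in graphs])
    return _MergedGraph(gene_idx, adj, node_sample, node_local)


def sample_training_subgraph(
    graphs: list[TranscriptGraph], roots_per_sample: int, hops_context: int, rng
) -> _MergedGraph:
    """Per-sample root sampling with ``hops_context``-hop neighborhoods,
    merged as a disjoint union (memory-bounded training input)."""
    kept_graphs = []
    for g in graphs:
        n = g.n_nodes
        if roots_per_sample >= n:
            kept_graphs.append(g)
            continue
        roots = rng.choice(n, size=roots_per_sample, replace=False)
        frontier = np.zeros(n, dtype=bool)
        frontier[roots] = True
        reach = frontier.copy()
        for _ in range(hops_context):
            nxt = (g.adj @ frontier.astype(np.int8)) > 0
            frontier = nxt & ~reach
            reach |= nxt
        keep = np.flatnonzero(reach)
        sub = TranscriptGraph(
            g.sample_id,
            g.xy[keep],
            g.gene_idx[keep],
            g.adj[keep][:, keep].tocsr(),
            g.source_rows[keep],
        )
        kept_graphs.append(sub)
    return merge_graphs(kept_graphs)


def _sample_neighbors(adj: sp.csr_matrix, nodes: np.ndarray, fanout: int, rng) -> np.ndarray:
    """Sample ``fanout`` neighbors (with replacement) per node; isolated nodes
    fall back to themselves."""
    indptr, indices = adj.indptr, adj.indices
    deg = indptr[nodes + 1] - indptr[nodes]
    out = np.repeat(nodes, fanout).reshape(len(nodes), fanout)
    has = deg > 0
    if has.any():
        offs = rng.integers(0, deg[has, None], size=(int(has.sum()), fanout))
        out[has] = indices[indptr[nodes[has], None] + offs]
    return out


def _forward_batch(model: EmbeddingModel, g: _MergedGraph, nodes: np.ndarray, rng):
    """Sampled forward pass; returns embeddings and the cache for backprop."""
    P = model.params
    f1, f2 = model.fanout
    n1 = _sample_neighbors(g.adj, nodes, f1, rng)  # (m, f1)
    need = np.concatenate([nodes, n1.ravel()])
    uniq, inv = np.unique(need, return_inverse=True)
    n2 = _sample_neighbors(g.adj, uniq, f2, rng)  # (|U|, f2)
    gU = g.gene_idx[uniq]
    gN2 = g.gene_idx[n2]
    a_self = P["W1s"][gU]
    a_neigh = P["W1n"][gN2].mean(axis=1)
    pre = a_self + a_neigh + P["b1"]
    h1 = np.maximum(pre, 0.0)
    m = len(nodes)
    pos_self = inv[:m]
    pos_n1 = inv[m:].reshape(m, f1)
    h1_self = h1[pos_self]
    h1_nmean = h1[pos_n1].mean(axis=1)
    z = h1_self @ P["W2s"] + h1_nmean @ P["W2n"] + P["b2"]
    cache = dict(
        mask=pre > 0, gU=gU, gN2=gN2, pos_self=pos_self, pos_n1=pos_n1,
        h1=h1, h1_self=h1_self, h1_nmean=h1_nmean, n_uniq=len(uniq),
    )
    return z, cache


def _scatter_rows(n_rows: int, idx: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Row-wise scatter-add (out[idx[i]] += vals[i]) via sparse accumulation."""
    k = len(idx)
    A = sp.csr_matrix(
        (np.ones(k, dtype=np.float32), (idx, np.arange(k))), shape=(n_rows, k)
    )
    return A @ vals


def _backward_batch(model: EmbeddingModel, cache: dict, dz: np.ndarray, grads: dict) -> None:
    P = model.params
    f1 = model.fanout[0]
    f2 = model.fanout[1]
    dz = dz.astype(np.float32)
    grads["W2s"] += cache["h1_self"].T @ dz
    grads["W2n"] += cache["h1_nmean"].T @ dz
    grads["b2"] += dz.sum(axis=0)
    n_uniq = cache["n_uniq"]
    dh1 = _scatter_rows(n_uniq, cache["pos_self"], dz @ P["W2s"].T)
    dn1 = (dz @ P["W2n"].T) / f1
    dh1 += _scatter_rows(n_uniq, cache["pos_n1"].ravel(), np.repeat(dn1, f1, axis=0))
    dpre = (dh1 * cache["mask"]).astype(np.float32)
    grads["W1s"] += _scatter_rows(model.n_genes, cache["gU"], dpre)
    grads["b1"] += dpre.sum(axis=0)
    dneigh = np.repeat(dpre / f2, f2, axis=0)
    grads["W1n"] += _scatter_rows(model.n_genes, cache["gN2"].ravel(), dneigh)


def train_embedding(graphs: list[TranscriptGraph], model: EmbeddingModel) -> EmbeddingModel:
    """Unsupervised link-prediction training on the merged per-sample subgraphs.

    Positive pairs are observed edges; negatives are uniform random node
    pairs re-drawn when they collide with a true edge (on these sparse
    graphs collisions are rare).  Reports the final-epoch training accuracy
    on the binary edge/non-edge task.
    """
    rng = np.random.default_rng(model.seed)
    g = sample_training_subgraph(graphs, model.roots_per_sample, model.hops + 1, rng)
    if g.adj.nnz == 0:
        raise ValueError("training graph has no edges: no positive pairs to learn from")
    coo = sp.triu(g.adj, k=1).tocoo()
    edges = np.column_stack([coo.row, coo.col]).astype(np.int64)
    n_pairs = model.pairs_per_epoch or len(edges)
    n_nodes = g.adj.shape[0]
    edge_keys = set((edges[:, 0] * n_nodes + edges[:, 1]).tolist())
    edge_keys.update((edges[:, 1] * n_nodes + edges[:, 0]).tolist())

    # Adam state
    mstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    vstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    last_correct = last_total = 0

    for epoch in range(model.epochs):
        sel = rng.choice(len(edges), size=min(n_pairs, len(edges)), replace=False)
        ep_loss, ep_correct, ep_total = 0.0, 0, 0
        bs = max(1, model.batch_size // (1 + model.negatives_per_edge))
        n_batches = 0
        for start in range(0, len(sel), bs):
            batch = edges[sel[start : start + bs]]
            u, v = batch[:, 0], batch[:, 1]
            nu = np.repeat(u, model.negatives_per_edge)
            nv = rng.integers(0, n_nodes, size=len(nu))
            for _ in range(3):
                keys = (nu * n_nodes + nv).tolist()
                bad = np.fromiter(
                    (k in edge_keys for k in keys), dtype=bool, count=len(keys)
                ) | (nu == nv)
                if not bad.any():
                    break
                nv[bad] = rng.integers(0, n_nodes, size=int(bad.sum()))
            pair_u = np.concatenate([u, nu])
            pair_v = np.concatenate([v, nv])
            y = np.concatenate([np.ones(len(u)), np.zeros(len(nu))]).astype(np.float32)

            # forward on deduplicated nodes, then map pairs back
            nodes_all = np.concatenate([pair_u, pair_v])
            uniq_nodes, inv_pairs = np.unique(nodes_all, return_inverse=True)
            z, cache = _forward_batch(model, g, uniq_nodes, rng)
            k = len(pair_u)
            iu, iv = inv_pairs[:k], inv_pairs[k:]
            zu, zv = z[iu], z[iv]
            s = np.einsum("ij,ij->i", zu, zv)
            p = 1.0 / (1.0 + np.exp(-s))
            ep_loss += float(-np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12)))
            ep_correct += int(((p > 0.5) == (y > 0.5)).sum())
            ep_total += len(y)

            ds = (p - y).astype(np.float32) / len(y)
            dz = np.zeros_like(z)
            np.add.at(dz, iu, ds[:, None] * zv)
            np.add.at(dz, iv, ds[:, None] * zu)
            grads = {kk: np.zeros_like(vv) for kk, vv in model.params.items()}
            _backward_batch(model, cache, dz, grads)
            step += 1
            n_batches += 1
            for kk in model.params:
                mstate[kk] = beta1 * mstate[kk] + (1 - beta1) * grads[kk]
                vstate[kk] = beta2 * vstate[kk] + (1 - beta2) * grads[kk] ** 2
                mhat = mstate[kk] / (1 - beta1**step)
                vhat = vstate[kk] / (1 - beta2**step)
                model.params[kk] -= model.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.loss_trace.append(ep_loss / max(1, n_batches))
        last_correct, last_total = ep_correct, ep_total
    model.train_accuracy = last_correct / max(1, last_total)
    return model


def embed_nodes(model: EmbeddingModel, graph: TranscriptGraph) -> np.ndarray:
    """Deterministic full-neighborhood (eval-mode) embedding of every node."""
    P = model.params
    n = graph.n_nodes
    if n == 0:
        return np.zeros((0, model.out_dim), dtype=np.float32)
    deg = np.asarray(graph.adj.sum(axis=1)).ravel()
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
    Dinv = sp.diags(inv_deg)
    X_self = P["W1s"][graph.gene_idx]
    Xn = P["W1n"][graph.gene_idx]
    mean_neigh = (Dinv @ graph.adj) @ Xn
    iso = deg == 0  # isolated nodes aggregate themselves (matches training fallback)
    mean_neigh[iso] = Xn[iso]
    h1 = np.maximum(X_self + mean_neigh + P["b1"], 0.0)
    mean_h1 = (Dinv @ graph.adj) @ h1
    mean_h1[iso] = h1[iso]
    return (h1 @ P["W2s"] + mean_h1 @ P["W2n"] + P["b2"]).astype(np.float32)


# --------------------------------------------------------------------------
# clustering + hexbin consensus
# --------------------------------------------------------------------------


def embed_and_cluster(
    graphs: list[TranscriptGraph],
    model: EmbeddingModel,
    k: int = 12,
    seed: int = 0,
    subsample: int | None = None,
) -> tuple[list[pd.DataFrame], GaussianMixture]:
    """Embed all nodes, fit one Gaussian mixture on the pooled embeddings,
    and hard-label every transcript (argmax posterior), labels 1..k.

    Returns one frame per graph with columns x, y, niche, and the fitted
    mixture.  ``subsample`` optionally caps the number of embeddings used to
    fit the mixture (all nodes are always labeled).
    """
    embs = [embed_nodes(model, g) for g in graphs]
    pooled = np.vstack([e for e in embs if len(e)])
    if k > len(pooled):
        raise ValueError("k exceeds the number of nodes")
    fit_on = pooled
    rng = np.random.default_rng(seed)
    if subsample is not None and subsample < len(pooled):
        fit_on = pooled[rng.choice(len(pooled), size=subsample, replace=False)]
    # a well-converged k-means solution (multiple restarts) seeds the mixture:
    # single-restart initializations make the component allocation a lottery
    # between partition-aligned and likelihood-favored but fragmented optima
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(fit_on)
    gmm = GaussianMixture(
        n_components=k, covariance_type="full", means_init=km.cluster_centers_,
        random_state=seed, tol=1e-4, reg_covar=1e-5,
    )
    gmm.fit(fit_on)
    out = []
    for g, e in zip(graphs, embs):
        labels = gmm.predict(e) + 1 if len(e) else np.empty(0, dtype=int)
        out.append(
            pd.DataFrame(
                {
                    "x_location": g.xy[:, 0],
                    "y_location": g.xy[:, 1],
                    "niche": labels,
                    "sample_id": g.sample_id,
                },
                index=g.source_rows,
            )
        )
    return out, gmm


DEFAULT_BIN_WIDTH = 5.0
DEFAULT_MIN_BIN_COUNT = 10


def _hex_axial(x, y, size):
    """Pointy-top axial hex coordinates (origin-anchored) with cube rounding."""
    q = (math.sqrt(3) / 3 * x - y / 3) / size
    r = (2.0 / 3.0 * y) / size
    # cube round
    xf, zf = q, r
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def _hex_center(q, r, size):
    x = size * math.sqrt(3) * (q + r / 2.0)
    y = size * 1.5 * r
    return x, y


def hexbin_summarize(
    labeled: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_count: int = DEFAULT_MIN_BIN_COUNT,
) -> pd.DataFrame:
    """Hexagonal majority-vote consensus of per-transcript niche labels.

    Pointy-top hexes anchored at the coordinate origin; ``bin_width`` is the
    horizontal center-to-center spacing (same μm units as the transcripts).
    Bins with fewer than ``min_count`` transcripts are dropped; label ties
    break toward the smallest label index.
    """
    size = bin_width / math.sqrt(3)
    q, r = _hex_axial(
        labeled["x_location"].to_numpy(float), labeled["y_location"].to_numpy(float), size
    )
    df = pd.DataFrame({"q": q, "r": r, "niche": labeled["niche"].to_numpy()})
    counts = df.groupby(["q", "r", "niche"], sort=True).size().rename("n").reset_index()
    totals = counts.groupby(["q", "r"])["n"].sum()
    # majority with smallest-label tie-break: sort by count desc then label asc
    counts = counts.sort_values(["q", "r", "n", "niche"], ascending=[True, True, False, True])
    top = counts.drop_duplicates(["q", "r"], keep="first").set_index(["q", "r"])
    top["count"] = totals
    top = top[top["count"] >= min_count].reset_index()
    cx, cy = _hex_center(top["q"].to_numpy(float), top["r"].to_numpy(float), size)
    return pd.DataFrame(
        {
            "q": top["q"],
            "r": top["r"],
            "x_center": cx,
            "y_center": cy,
            "count": top["count"].astype(int),
            "niche": top["niche"].astype(int),
        }
    )


def assign_cells_to_transcript_niches(
    cells: pd.DataFrame, hexmap: pd.DataFrame
) -> pd.DataFrame:
    """Assign each cell the niche of its nearest retained hex-bin centroid.

    Returns a frame (indexed like ``cells``) with ``transcript_niche`` (0 =
    unassigned, when the sample has no retained bins) and the distance to the
    chosen bin.
    """
    niche = np.zeros(len(cells), dtype=int)
    dist = np.full(len(cells), np.nan)
    if len(hexmap):
        tree = cKDTree(hexmap[["x_center", "y_center"]].to_numpy(float))
        d, nn = tree.query(cells[["x_centroid", "y_centroid"]].to_numpy(float))
        niche = hexmap["niche"].to_numpy()[nn]
        dist = d
    return pd.DataFrame(
        {"cell_id": cells["cell_id"].to_numpy(), "transcript_niche": niche, "bin_distance": dist}
    )
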