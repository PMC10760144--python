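"""Cell-based spatial niches: neighborhood cell-type composition + k-means.

For every cell, the cell-type composition of its 25 spatially closest
neighbors (same sample, the cell itself included in its own neighborhood)
is computed, and cells are partitioned into 12 niches by k-means on those
composition vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

DEFAULT_K_NEIGHBORS = 25
DEFAULT_K_NICHES = 12


def neighborhood_composition(
    cells: pd.DataFrame,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    include_self: bool = True,
    type_vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell neighborhood cell-type composition (rows sum to 1).

    Neighbors are the Euclidean k nearest centroids within the same sample.
    With ``include_self`` the query cell counts as one of its k neighbors
    (the neighborhood-aggregate convention of the reference implementation).
    """
    if type_vocabulary is None:
        type_vocabulary = sorted(cells["cell_type"].unique())
    type_pos = {t: i for i, t in enumerate(type_vocabulary)}
    comp = np.zeros((len(cells), len(type_vocabulary)))
    tcodes = cells["cell_type"].map(type_pos).to_numpy()

    for sample, idx in cells.groupby("sample_id", sort=False).indices.items():
        xy = cells.iloc[idx][["x_centroid", "y_centroid"]].to_numpy(dtype=float)
        if len(idx) <= k_neighbors:
            raise ValueError(
                f"sample {sample!r} has {len(idx)} cells; need > {k_neighbors} for "
                "neighborhood composition"
            )
        tree = cKDTree(xy)
        if include_self:
            _, nn = tree.query(xy, k=k_neighbors)
        else:
            _, nn = tree.query(xy, k=k_neighbors + 1)
            nn = nn[:, 1:]
        codes = tcodes[idx][nn]  # (n, k) type codes of neighbors
        for j in range(len(type_vocabulary)):
            comp[idx, j] = (codes == j).mean(axis=1)
    return pd.DataFrame(comp, index=pd.Index(cells["cell_id"], name="cell_id"), columns=type_vocabulary)


def cluster_niches(
    compositions: pd.DataFrame, k_niches: int = DEFAULT_K_NICHES, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means (k-means++ init, fixed seed) over composition vectors.

    Returns per-cell labels 1..k and the per-niche mean composition.
    """
    if k_niches > len(compositions):
        raise ValueError("k_niches exceeds the number of cells")
    km = KMeans(n_clusters=k_niches, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(compositions.to_numpy()) + 1
    labels = pd.Series(labels, index=compositions.index, name="cell_niche")
    means = pd.DataFrame(
        km.cluster_centers_, index=pd.RangeIndex(1, k_niches + 1, name="niche"),
        columns=compositions.columns,
    )
    return labels, means


def airway_niche_ids(niche_means: pd.DataFrame, airway_types, frac: float = 0.25) -> list[int]:
    """Niches whose mean composition is dominated by airway epithelial types.

    Used by the airspace filters to drop lumens lined by airway niches.
    """
    cols = [t for t in airway_types if t in niche_means.columns]
    score = niche_means[cols].sum(axis=1)
    return list(niche_means.index[score >= frac])
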