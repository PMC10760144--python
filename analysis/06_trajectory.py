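"""Pseudotime over the remodeling gradient.

Orders the 300 planted airspaces by composition-space principal-curve
pseudotime and compares the ordering with the planted severity.
"""

import sys
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from airscape import synthdata as sd, trajectory as tj

OUT = Path(__file__).resolve().parents[1] / "results"


def airspace_compositions(cells, truth):
    c = cells.copy()
    c["lumen_id"] = truth.cell_lumen_id.loc[c.cell_id].to_numpy()
    comp = c.pivot_table(index="lumen_id", columns="cell_type", aggfunc="size", fill_value=0)
    return comp.div(comp.sum(axis=1), axis=0)


def main(seed: int = 0) -> None:
    cfg = sd.small_test_config(seed=seed)
    tx, cells, truth = sd.generate_remodeling_gradient(cfg, n_airspaces=300)
    comp = airspace_compositions(cells, truth)
    severity = pd.Series({p.lumen_id: p.severity for p in truth.lumens}).loc[comp.index]

    scores, evr = tj.composition_pca(comp)
    print(f"composition PCA, explained variance of first 3 PCs: "
          f"{evr[0]:.2f} {evr[1]:.2f} {evr[2]:.2f}")
    fit = tj.fit_pseudotime(scores, compositions=comp, seed=seed)
    rho = spearmanr(fit.pseudotime, severity).statistic
    print(f"pseudotime vs planted severity: Spearman |rho| = {abs(rho):.3f} "
          f"({fit.n_iterations} principal-curve iterations, start cluster {fit.start_cluster})")

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"lumen_id": comp.index, "pseudotime": fit.pseudotime, "severity": severity.to_numpy()}
    ).to_csv(OUT / "pseudotime.csv", index=False)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
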