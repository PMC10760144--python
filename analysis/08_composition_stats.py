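"""Composition and pseudobulk statistics.

Logit-proportion ANOVA across disease groups at the study's group sizes
(6 unaffected / 9 less fibrotic / 9 more fibrotic), regression of
proportions on pathology scores, representative-gene detection for planted
niches, and voom-style pseudobulk differential expression across simulated
pathology-annotation instances.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from airscape import compstats as cs, qc, synthdata as sd

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    rng = np.random.default_rng(seed)

    # disease-group composition ANOVA with a planted 2-fold shift
    counts, groups = sd.simulate_group_compositions(seed, fold_change=2.0)
    props, totals = cs.proportions_from_counts(counts)
    anova = cs.composition_anova(props, groups, totals, fdr=0.05)
    print(f"ANOVA: shifted type detected (FDR<0.05): {bool(anova.loc['type_00','significant'])}; "
          f"{int(anova.significant.sum())} / {len(anova)} types significant")

    # pathology-score regression on logit proportions
    scores = pd.Series(rng.uniform(0, 12, len(props)), index=props.index)
    shifted = props.copy()
    z = cs.logit_transform(shifted["type_01"].to_numpy(), totals.to_numpy())
    z = z + 0.15 * scores.to_numpy()
    shifted["type_01"] = 1 / (1 + np.exp(-z))
    shifted = shifted.div(shifted.sum(axis=1), axis=0)
    reg = cs.covariate_regression(shifted, scores, unit_totals=totals, fdr=0.01)
    print(f"score regression: planted type significant: "
          f"{bool(reg.loc['type_01','significant'])} (slope {reg.loc['type_01','slope']:.2f})")

    # representative genes of planted niches (truth transcript niche labels)
    cfg = sd.small_test_config(seed=seed)
    tx, cells, truth = sd.generate_tissue(cfg)
    kept, _ = qc.filter_transcripts(tx)
    assigned = kept[kept.cell_id.notna()].copy()
    assigned["niche"] = assigned.cell_id.map(truth.niche_label)
    markers = cs.niche_marker_genes(assigned, niche_column="niche")
    for niche, program in sd.NICHE_PROGRAMS.items():
        sub = markers[markers.niche == niche]
        if len(sub):
            top = sub.iloc[0]
            hit = top.gene in program
            print(f"  {niche}: top representative gene {top.gene} "
                  f"({'planted program gene' if hit else 'off-program'})")

    # pseudobulk DE across annotation types with a planted 4-fold marker
    genes = [f"G{i:03d}" for i in range(80)]
    base = rng.gamma(2.0, 50.0, len(genes))
    rows, ann, ncell = [], [], []
    for t in ("fibroblastic focus", "granuloma", "severe fibrosis", "normal alveoli"):
        for _ in range(5):
            mu = base.copy()
            if t == "fibroblastic focus":
                mu[0] *= 4.0
            lib = rng.uniform(0.5, 2.0)
            rows.append(rng.poisson(mu * lib * rng.gamma(8.0, 1 / 8.0, len(genes))))
            ann.append(t)
            ncell.append(int(rng.integers(50, 300)))
    pb = pd.DataFrame(rows, columns=genes, index=[f"inst{i:02d}" for i in range(len(rows))])
    de = cs.pseudobulk_de_annotations(
        pb, pd.Series(ann, index=pb.index), pd.Series(ncell, index=pb.index),
        epithelial_types=("normal alveoli",),
    )
    ff = de["one_vs_rest"].query("annotation == 'fibroblastic focus'").nsmallest(1, "pvalue")
    print(f"pseudobulk DE: top gene for fibroblastic focus = {ff.gene.iloc[0]} "
          f"(log2FC {ff.log2fc.iloc[0]:.2f})")

    OUT.mkdir(parents=True, exist_ok=True)
    anova.to_csv(OUT / "composition_anova.tsv", sep="\t")
    reg.to_csv(OUT / "score_regression.tsv", sep="\t")
    markers.to_csv(OUT / "niche_marker_genes.tsv", sep="\t", index=False)
    de["one_vs_rest"].to_csv(OUT / "pathology_de.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
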