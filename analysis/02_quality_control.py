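"""Transcript and cell QC on the simulated tissue.

Drops low-quality (qv < 20) and blank-probe transcripts, builds the
nuclei-restricted count matrix, applies the four cell filters, and reports
the principal-component selection rule on the normalized matrix.
"""

import sys
from pathlib import Path

import pandas as pd

from airscape import qc, synthdata as sd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main(seed: int = 0) -> None:
    cfg = sd.small_test_config(seed=seed)
    tx, cells, truth = sd.generate_tissue(cfg)

    kept, removed = qc.filter_transcripts(tx)
    print(f"transcripts: {len(tx):,} -> {len(kept):,} "
          f"(removed {removed['low_qv']:,} low-qv, {removed['blank']:,} blank)")

    cells_qc = qc.compute_cell_qc(tx, cells)
    cells_kept, report = qc.filter_cells(cells_qc)
    print("cell QC removals:", {k: v for k, v in report.items() if k != "kept"})
    print(f"cells kept: {report['kept']:,} / {len(cells):,}")

    adata = qc.build_count_matrix(kept, cells_kept, gene_panel=cfg.gene_panel)
    Xn, zero_cells = qc.normalize_log1p(adata.X)
    scores, evr, n_pcs = qc.run_pca(Xn, n_components=50, seed=seed)
    print(f"PC selection: {n_pcs} PCs "
          f"(cumulative variance at selection {evr[:n_pcs].sum():.3f})")

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report, index=[0]).to_csv(OUT / "qc_cell_report.tsv", sep="\t", index=False)
    cells_kept.to_csv(OUT / "cells_qc.csv", index=False)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
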