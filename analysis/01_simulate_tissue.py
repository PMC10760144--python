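"""Generate the synthetic study data.

Two Xenium-like tissue cores — one unaffected, one fibrotic (mirroring
paired sampling of PF lungs) — plus a 300-airspace remodeling gradient used
by the trajectory and association stages.  Tables land under results/data/.
"""

import sys
from pathlib import Path

from airscape import synthdata as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 0) -> None:
    cfg = sd.small_test_config(seed=seed)
    tx, cells, truth = sd.generate_tissue(cfg)
    sd.write_tables(OUT / "tissue", tx, cells, truth)
    print(f"tissue: {len(tx):,} transcripts, {len(cells):,} cells, "
          f"{len(truth.lumens)} planted lumens across {cfg.n_samples} samples")
    print("planted niche shares:")
    print(truth.niche_label.value_counts(normalize=True).round(3).to_string())

    gtx, gcells, gtruth = sd.generate_remodeling_gradient(cfg, n_airspaces=300)
    sd.write_tables(OUT / "gradient", gtx, gcells, gtruth, parquet=False)
    print(f"gradient: {len(gtx):,} transcripts over 300 airspaces, "
          f"severity range {gtruth.severity.min():.2f}-{gtruth.severity.max():.2f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
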