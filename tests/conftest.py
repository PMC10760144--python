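import numpy as np
import pandas as pd
import pytest

from airscape import qc, synthdata as sd


@pytest.fixture(scope="session")
def tissue():
    """Paired unaffected/fibrotic synthetic cores (desk-scale conditions)."""
    cfg = sd.small_test_config(seed=0)
    tx, cells, truth = sd.generate_tissue(cfg)
    return cfg, tx, cells, truth


@pytest.fixture(scope="session")
def tissue_qc(tissue):
    cfg, tx, cells, truth = tissue
    kept, removed = qc.filter_transcripts(tx)
    cells_qc = qc.compute_cell_qc(tx, cells)
    cells_kept, report = qc.filter_cells(cells_qc)
    return kept, removed, cells_kept, report


@pytest.fixture(scope="session")
def gradient():
    """300-airspace remodeling gradient with planted severity and dynamics."""
    cfg = sd.small_test_config(seed=0)
    tx, cells, truth = sd.generate_remodeling_gradient(cfg, n_airspaces=300)
    return cfg, tx, cells, truth


@pytest.fixture(scope="session")
def gradient_composition(gradient):
    cfg, tx, cells, truth = gradient
    c = cells.copy()
    c["lumen_id"] = truth.cell_lumen_id.loc[c.cell_id].to_numpy()
    comp = c.pivot_table(index="lumen_id", columns="cell_type", aggfunc="size", fill_value=0)
    comp = comp.div(comp.sum(axis=1), axis=0)
    severity = pd.Series({p.lumen_id: p.severity for p in truth.lumens}).loc[comp.index]
    return comp, severity


def tiny_config(seed=0, **kw):
    """Minimal tissue for fast unit tests (single small core)."""
    layout = sd.LayoutConfig(n_alveoli=2, n_airways=0, n_vessels=1, n_fibrotic=1,
                             macrophage_lumen_fraction=0.0)
    args = dict(seed=seed, n_samples=1, core_diameter_mm=0.7, layout=layout)
    args.update(kw)
    return sd.SyntheticConfig(**args)


@pytest.fixture(scope="session")
def tiny_tissue():
    cfg = tiny_config(seed=3)
    tx, cells, truth = sd.generate_tissue(cfg)
    return cfg, tx, cells, truth


def nb_counts(rng, mu, size_disp=5.0):
    """Negative-binomial draws via the gamma-Poisson mixture."""
    lam = rng.gamma(size_disp, np.asarray(mu) / size_disp)
    return rng.poisson(lam).astype(float)
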