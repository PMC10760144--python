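"""Synthetic imaging-based spatial transcriptomics tissue generator.

Emulates the structure of a Xenium-style run on distal lung tissue: circular
tissue cores populated with alveoli (annular walls of alveolar cell types
around empty lumens), conducting airways, blood vessels, fibrotic patches and
interstitium.  Each cell emits transcripts from a cell-type-specific
multinomial over a gene panel that includes blank (negative-control) probes;
transcripts carry positions, a phred-like quality value ``qv``, a cell
assignment and a nucleus-overlap flag, mirroring the per-transcript output of
the instrument.

Ground truth (cell types, structure-derived niche labels, lumen geometry,
per-airspace remodeling severity, and the curve family of severity-dynamic
genes) is returned alongside the tables so every downstream stage of the
pipeline can be validated without real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# cell-type programs
# --------------------------------------------------------------------------

# ~19 synthetic types mirroring the major level-2 annotation groups of the
# distal lung (alveolar/airway epithelium, endothelium, mesenchyme, myeloid,
# lymphoid).  The first marker of each type is the canonical field name.
DEFAULT_TYPE_MARKERS: dict[str, list[str]] = {
    "AT1": ["AGER", "PDPN", "AT1_M3", "AT1_M4", "AT1_M5", "AT1_M6"],
    "AT2": ["SFTPC", "SFTPB", "AT2_M3", "AT2_M4", "AT2_M5", "AT2_M6"],
    "Transitional AT2": ["KRT8", "TAT2_M2", "TAT2_M3", "TAT2_M4", "TAT2_M5", "TAT2_M6"],
    "KRT5-/KRT17+": ["KRT17", "MMP7", "ABB_M3", "ABB_M4", "ABB_M5", "ABB_M6"],
    "Basal": ["KRT5", "TP63", "BAS_M3", "BAS_M4", "BAS_M5", "BAS_M6"],
    "Ciliated": ["FOXJ1", "CIL_M2", "CIL_M3", "CIL_M4", "CIL_M5", "CIL_M6"],
    "Differentiating ciliated": ["DCIL_M1", "DCIL_M2", "DCIL_M3", "DCIL_M4", "DCIL_M5", "DCIL_M6"],
    "MUC5B+": ["MUC5B", "MUC_M2", "MUC_M3", "MUC_M4", "MUC_M5", "MUC_M6"],
    "SCGB3A2+/SCGB1A1+": ["SCGB3A2", "SCGB1A1", "SCG_M3", "SCG_M4", "SCG_M5", "SCG_M6"],
    "Capillary": ["CA4", "PECAM1", "CAP_M3", "CAP_M4", "CAP_M5", "CAP_M6"],
    "Arteriole": ["GJA5", "ART_M2", "ART_M3", "ART_M4", "ART_M5", "ART_M6"],
    "Venous": ["COL15A1", "VEN_M2", "VEN_M3", "VEN_M4", "VEN_M5", "VEN_M6"],
    "Lymphatic": ["PROX1", "LYM_M2", "LYM_M3", "LYM_M4", "LYM_M5", "LYM_M6"],
    "Alveolar fibroblast": ["SPINT2", "AFB_M2", "AFB_M3", "AFB_M4", "AFB_M5", "AFB_M6"],
    "Activated fibroblast": ["CTHRC1", "FAP", "COL1A1", "ACF_M4", "ACF_M5", "ACF_M6"],
    "Smooth muscle": ["ACTA2", "MYH11", "SMC_M3", "SMC_M4", "SMC_M5", "SMC_M6"],
    "FABP4+ macrophage": ["FABP4", "FMAC_M2", "FMAC_M3", "FMAC_M4", "FMAC_M5", "FMAC_M6"],
    "SPP1+ macrophage": ["SPP1", "SMAC_M2", "SMAC_M3", "SMAC_M4", "SMAC_M5", "SMAC_M6"],
    "Interstitial macrophage": ["IMAC_M1", "IMAC_M2", "IMAC_M3", "IMAC_M4", "IMAC_M5", "IMAC_M6"],
    "T-cell": ["CD3E", "TCL_M2", "TCL_M3", "TCL_M4", "TCL_M5", "TCL_M6"],
    "B-cell": ["MS4A1", "BCL_M2", "BCL_M3", "BCL_M4", "BCL_M5", "BCL_M6"],
}

IMMUNE_TYPES = (
    "FABP4+ macrophage",
    "SPP1+ macrophage",
    "Interstitial macrophage",
    "T-cell",
    "B-cell",
)

ALVEOLAR_TYPES = ("AT1", "AT2", "Transitional AT2", "Alveolar fibroblast")
AIRWAY_TYPES = (
    "Basal",
    "Ciliated",
    "Differentiating ciliated",
    "MUC5B+",
    "SCGB3A2+/SCGB1A1+",
)
NONCAP_ENDO_TYPES = ("Arteriole", "Venous", "Lymphatic")

# structure-class cell mixtures (planted niche programs)
HOMEOSTATIC_ALVEOLAR_MIX = {
    "AT1": 0.16,
    "AT2": 0.20,
    "Capillary": 0.20,
    "Alveolar fibroblast": 0.16,
    "Interstitial macrophage": 0.10,
    "T-cell": 0.06,
    "B-cell": 0.04,
    "Venous": 0.08,
}
REMODELED_ALVEOLAR_MIX = {
    "Transitional AT2": 0.26,
    "KRT5-/KRT17+": 0.16,
    "SCGB3A2+/SCGB1A1+": 0.14,
    "MUC5B+": 0.06,
    "Activated fibroblast": 0.20,
    "Venous": 0.08,
    "SPP1+ macrophage": 0.06,
    "AT2": 0.04,
}
AIRWAY_MIX = {
    "Basal": 0.22,
    "Ciliated": 0.28,
    "Differentiating ciliated": 0.10,
    "MUC5B+": 0.15,
    "SCGB3A2+/SCGB1A1+": 0.15,
    "Smooth muscle": 0.10,
}
VESSEL_MIX = {
    "Arteriole": 0.25,
    "Venous": 0.32,
    "Lymphatic": 0.08,
    "Smooth muscle": 0.30,
    "Capillary": 0.05,
}
FIBROTIC_MIX = {
    "Activated fibroblast": 0.50,
    "Alveolar fibroblast": 0.08,
    "SPP1+ macrophage": 0.10,
    "T-cell": 0.16,
    "B-cell": 0.08,
    "Venous": 0.08,
}
LUMEN_MACROPHAGE_MIX = {"FABP4+ macrophage": 0.6, "SPP1+ macrophage": 0.4}

# Niche-level molecular programs: genes expressed by resident cells of a
# spatial niche regardless of type (paracrine/matrix programs — surfactant
# milieu in healthy parenchyma, collagen/matrix genes across fibrotic tissue,
# mucins in airways).  These give niches their molecular signature on top of
# cell-type identity, which is what cell-agnostic niche detection keys on.
NICHE_PROGRAMS: dict[str, list[str]] = {
    "alveolar": ["SFTPA1", "SFTPD", "ALV_N3", "ALV_N4", "ALV_N5", "ALV_N6"],
    "remodeled_alveolar": ["SERPINE1", "CDKN1A", "RMD_N3", "RMD_N4", "RMD_N5", "RMD_N6"],
    "airway": ["MUC5AC", "SERPINB3", "AWY_N3", "AWY_N4", "AWY_N5", "AWY_N6"],
    "vascular": ["VWF", "CLDN5", "VAS_N3", "VAS_N4", "VAS_N5", "VAS_N6"],
    "fibrotic": ["COL3A1", "FN1", "FIB_N3", "FIB_N4", "FIB_N5", "FIB_N6"],
    "airspace_macrophage": ["MARCO", "MRC1", "MAC_N3", "MAC_N4", "MAC_N5", "MAC_N6"],
}


def default_gene_panel(n_housekeeping: int = 40, n_blanks: int = 20) -> tuple[list[str], list[str]]:
    """Marker genes for every type plus shared housekeeping genes and blank probes.

    Returns ``(target_genes, blank_names)``.
    """
    genes: list[str] = []
    for markers in DEFAULT_TYPE_MARKERS.values():
        genes.extend(markers)
    for prog in NICHE_PROGRAMS.values():
        genes.extend(prog)
    genes.extend(f"HK_{i:02d}" for i in range(1, n_housekeeping + 1))
    blanks = [f"BLANK-{i:04d}" for i in range(1, n_blanks + 1)]
    return genes, blanks


def default_cell_type_profiles(
    genes: list[str],
    marker_weight: float = 0.45,
    housekeeping_weight: float = 0.50,
) -> dict[str, np.ndarray]:
    """Multinomial expression weights per cell type over ``genes``.

    ``marker_weight`` of each type's emission mass sits on its own markers,
    ``housekeeping_weight`` on the shared housekeeping genes, and the
    remainder leaks uniformly across the whole panel (background noise).
    """
    gene_index = {g: i for i, g in enumerate(genes)}
    hk = [g for g in genes if g.startswith("HK_")]
    leak = 1.0 - marker_weight - housekeeping_weight
    profiles = {}
    for ctype, markers in DEFAULT_TYPE_MARKERS.items():
        w = np.full(len(genes), leak / len(genes))
        for m in markers:
            w[gene_index[m]] += marker_weight / len(markers)
        for g in hk:
            w[gene_index[g]] += housekeeping_weight / len(hk)
        profiles[ctype] = w / w.sum()
    return profiles


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class LayoutConfig:
    """Counts and size ranges (μm) for planted structures on one core."""

    n_alveoli: int = 30
    n_airways: int = 4
    n_vessels: int = 8
    n_fibrotic: int = 4
    alveolus_lumen_radius: tuple[float, float] = (55.0, 70.0)
    alveolus_wall: tuple[float, float] = (12.0, 16.0)
    airway_lumen_radius: tuple[float, float] = (55.0, 75.0)
    airway_wall: tuple[float, float] = (18.0, 24.0)
    vessel_lumen_radius: tuple[float, float] = (20.0, 35.0)
    vessel_wall: tuple[float, float] = (12.0, 18.0)
    fibrotic_radius: tuple[float, float] = (70.0, 100.0)
    # halo widths (μm): contiguous same-program tissue surrounding a structure
    remodeled_halo: float = 40.0
    airway_halo: float = 30.0
    vessel_halo: float = 35.0
    wall_cell_density: float = 1.0 / 80.0  # cells / μm² in structure walls
    interstitial_cell_density: float = 1.0 / 80.0
    macrophage_lumen_fraction: float = 0.2  # alveolar lumens with macrophage accumulation
    macrophage_lumen_density: float = 1.0 / 70.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic run (all lengths in μm)."""

    seed: int = 0
    n_samples: int = 2
    core_diameter_mm: float = 3.0  # real platform cores are 3 or 5 mm
    gene_panel: list[str] = field(default_factory=list)  # target genes
    blank_probes: list[str] = field(default_factory=list)
    cell_type_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    severity_range: tuple[float, float] = (0.0, 1.0)
    # per-sample overrides, e.g. [(0, 0), (1, 1)] for an unaffected/fibrotic
    # pair mirroring the paired less/more-fibrotic sampling of PF cores
    sample_severity_ranges: list[tuple[float, float]] | None = None
    transcripts_per_cell_mean: float = 60.0
    transcripts_per_cell_dispersion: float = 8.0  # NB size parameter
    low_qv_rate: float = 0.08  # fraction of transcripts with qv < 20
    blank_rate: float = 0.01
    nucleus_radius_um: float = 4.0
    cytoplasm_radius_um: float = 8.0
    nuclear_fraction: float = 0.55  # transcripts placed inside the nucleus
    misassignment_rate: float = 0.02  # transcript→neighboring-cell contamination
    unassigned_rate: float = 0.04  # transcripts with no cell id
    niche_program_weight: float = 0.40  # emission mass on niche-program genes

    def __post_init__(self) -> None:
        if not self.gene_panel:
            self.gene_panel, blanks = default_gene_panel()
            if not self.blank_probes:
                self.blank_probes = blanks
        if not self.cell_type_profiles:
            self.cell_type_profiles = default_cell_type_profiles(self.gene_panel)
        if not (0.0 <= self.blank_rate < 1.0):
            raise ValueError("blank_rate must be in [0, 1)")
        if self.core_diameter_mm <= 0:
            raise ValueError("core_diameter_mm must be positive")
        for t, w in self.cell_type_profiles.items():
            if abs(float(np.sum(w)) - 1.0) > 1e-8:
                raise ValueError(f"profile for {t!r} does not sum to 1")

    @property
    def core_radius_um(self) -> float:
        return self.core_diameter_mm * 1000.0 / 2.0


def small_test_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale configuration: a 1.2 mm core with a reduced structure count.

    Used by the analysis drivers and the test suite so full pipeline runs stay
    inside a single-CPU budget; structure geometry and statistical structure
    are identical to the default conditions, only core size and the number of
    planted structures shrink.
    """
    layout = LayoutConfig(n_alveoli=7, n_airways=2, n_vessels=3, n_fibrotic=3,
                          macrophage_lumen_fraction=0.6)
    kw = dict(seed=seed, n_samples=2, core_diameter_mm=1.3, layout=layout,
              sample_severity_ranges=[(0.0, 0.0), (1.0, 1.0)])
    kw.update(overrides)
    return SyntheticConfig(**kw)


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------


@dataclass
class PlantedLumen:
    lumen_id: int
    sample_id: str
    kind: str  # alveolus | airway | vessel
    center: tuple[float, float]
    radius: float
    wall: float
    severity: float | None = None  # alveoli only
    has_macrophages: bool = False

    def polygon_coords(self, n: int = 64) -> list[tuple[float, float]]:
        th = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return [
            (self.center[0] + self.radius * math.cos(a), self.center[1] + self.radius * math.sin(a))
            for a in th
        ]


@dataclass
class GroundTruth:
    cell_type: pd.Series  # indexed by cell_id
    niche_label: pd.Series  # indexed by cell_id
    lumens: list[PlantedLumen]
    severity: pd.Series  # indexed by cell_id (NaN outside graded alveoli)
    dynamic_genes: dict[str, dict]  # gene -> {family, params}
    cell_lumen_id: pd.Series | None = None  # gradient runs: planted airspace per cell

    def lumen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lumen_id": [p.lumen_id for p in self.lumens],
                "sample_id": [p.sample_id for p in self.lumens],
                "kind": [p.kind for p in self.lumens],
                "x": [p.center[0] for p in self.lumens],
                "y": [p.center[1] for p in self.lumens],
                "radius": [p.radius for p in self.lumens],
                "wall": [p.wall for p in self.lumens],
                "severity": [p.severity for p in self.lumens],
                "has_macrophages": [p.has_macrophages for p in self.lumens],
            }
        )


class StructurePlacementError(RuntimeError):
    """Raised when a planted structure cannot be placed without overlap."""


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


def _place_discs(
    rng: np.random.Generator,
    specs: list[tuple[str, float]],
    core_radius: float,
    margin: float = 15.0,
    max_tries: int = 4000,
) -> list[tuple[str, float, float, float]]:
    """Place non-overlapping discs (kind, outer_radius) inside the core.

    Returns (kind, x, y, outer_radius) with the core centered at
    (core_radius, core_radius); y grows downward by convention but the
    geometry is symmetric so no flip is needed.
    """
    placed: list[tuple[str, float, float, float]] = []
    cx = cy = core_radius
    for kind, r in specs:
        ok = False
        for _ in range(max_tries):
            ang = rng.uniform(0, 2 * math.pi)
            rad = (core_radius - r - margin) * math.sqrt(rng.uniform())
            x, y = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
            if all((x - px) ** 2 + (y - py) ** 2 > (r + pr + margin) ** 2 for _, px, py, pr in placed):
                placed.append((kind, x, y, r))
                ok = True
                break
        if not ok:
            raise StructurePlacementError(
                f"could not place structure of kind {kind!r} (outer radius {r:.0f} μm) "
                "within the retry budget; reduce layout counts or sizes"
            )
    return placed


def _annulus_points(rng, cx, cy, r_in, r_out, density):
    area = math.pi * (r_out**2 - r_in**2)
    n = rng.poisson(area * density)
    u = rng.uniform(r_in**2, r_out**2, n)
    rad = np.sqrt(u)
    th = rng.uniform(0, 2 * math.pi, n)
    return cx + rad * np.cos(th), cy + rad * np.sin(th)


def _disc_points(rng, cx, cy, r, density):
    return _annulus_points(rng, cx, cy, 0.0, r, density)


def _severity_mixture(s: float) -> dict[str, float]:
    """Interpolate the homeostatic → remodeled alveolar wall mixture at severity s."""
    types = sorted(set(HOMEOSTATIC_ALVEOLAR_MIX) | set(REMODELED_ALVEOLAR_MIX))
    mix = {
        t: (1.0 - s) * HOMEOSTATIC_ALVEOLAR_MIX.get(t, 0.0) + s * REMODELED_ALVEOLAR_MIX.get(t, 0.0)
        for t in types
    }
    z = sum(mix.values())
    return {t: v / z for t, v in mix.items()}


# --------------------------------------------------------------------------
# dynamic (severity-responsive) genes
# --------------------------------------------------------------------------


def default_dynamic_genes(rng: np.random.Generator) -> dict[str, dict]:
    """Severity-dynamic molecular programs on housekeeping-tier genes.

    Housekeeping genes are expressed by every type, so modulating them probes
    purely molecular (composition-independent) dynamics:
    10 flat controls, 5 increasing, 5 decreasing, 5 unimodal with known peak.
    """
    dyn: dict[str, dict] = {}
    for i in range(1, 11):
        dyn[f"HK_{i:02d}"] = {"family": "flat", "params": {}}
    for i in range(11, 16):
        dyn[f"HK_{i:02d}"] = {"family": "monotone", "params": {"beta": 1.5}}
    for i in range(16, 21):
        dyn[f"HK_{i:02d}"] = {"family": "monotone", "params": {"beta": -1.5}}
    peaks = [0.3, 0.4, 0.5, 0.6, 0.7]
    for i, pk in zip(range(21, 26), peaks):
        dyn[f"HK_{i:02d}"] = {"family": "unimodal", "params": {"peak": pk, "width": 0.18, "amp": 1.5}}
    return dyn


def _program_vector(niche: str, gene_index: dict[str, int], n_genes: int) -> np.ndarray:
    v = np.zeros(n_genes)
    genes = NICHE_PROGRAMS[niche]
    v[[gene_index[g] for g in genes]] = 1.0 / len(genes)
    return v


def _blend_niche_programs(
    W: np.ndarray,
    niche: np.ndarray,
    sev: np.ndarray,
    gene_index: dict[str, int],
    weight: float,
) -> np.ndarray:
    """Convex blend of type profiles with niche-program emissions.

    Severity-graded cells interpolate the healthy-alveolar → remodeled
    programs at their severity; other cells use their niche's program."""
    if weight <= 0:
        return W
    n_genes = W.shape[1]
    progs = {n: _program_vector(n, gene_index, n_genes) for n in NICHE_PROGRAMS}
    P = np.zeros_like(W)
    graded = np.isfinite(sev)
    for n in np.unique(niche[~graded]):
        P[(niche == n) & ~graded] = progs[n]
    if graded.any():
        sv = sev[graded][:, None]
        P[graded] = (1.0 - sv) * progs["alveolar"] + sv * progs["remodeled_alveolar"]
    return (1.0 - weight) * W + weight * P


def _dynamic_multiplier(info: dict, s: float) -> float:
    fam = info["family"]
    p = info["params"]
    if fam == "flat":
        return 1.0
    if fam == "monotone":
        return math.exp(p["beta"] * (s - 0.5))
    if fam == "unimodal":
        return 1.0 + p["amp"] * math.exp(-((s - p["peak"]) ** 2) / (2 * p["width"] ** 2))
    raise ValueError(f"unknown curve family {fam!r}")


# --------------------------------------------------------------------------
# core generation
# --------------------------------------------------------------------------


def _emit_transcripts(
    rng: np.random.Generator,
    config: SyntheticConfig,
    cells: pd.DataFrame,
    weights_per_cell: np.ndarray,
) -> pd.DataFrame:
    """Emit transcripts for every cell given its multinomial weights row."""
    genes = np.asarray(config.gene_panel, dtype=object)
    n_cells = len(cells)
    # NB(total) per cell
    size = config.transcripts_per_cell_dispersion
    mean = config.transcripts_per_cell_mean
    lam = rng.gamma(size, mean / size, n_cells)
    counts = rng.poisson(lam)
    total = int(counts.sum())

    cell_rep = np.repeat(np.arange(n_cells), counts)
    # gene draws: per cell multinomial == categorical draws with that cell's weights
    u = rng.uniform(size=total)
    cum = np.cumsum(weights_per_cell, axis=1)
    gene_idx = np.empty(total, dtype=np.int64)
    # vectorized per-cell searchsorted via offset trick
    pos = 0
    for ci, c in zip(np.arange(n_cells), counts):
        if c:
            gene_idx[pos : pos + c] = np.searchsorted(cum[ci], u[pos : pos + c], side="right")
            pos += c
    gene_idx = np.minimum(gene_idx, len(genes) - 1)
    feature = genes[gene_idx]

    # positions: nucleus or cytoplasm
    in_nucleus = rng.uniform(size=total) < config.nuclear_fraction
    r_nuc = config.nucleus_radius_um * np.sqrt(rng.uniform(size=total))
    r_cyt = np.sqrt(
        rng.uniform(config.nucleus_radius_um**2, config.cytoplasm_radius_um**2, total)
    )
    rad = np.where(in_nucleus, r_nuc, r_cyt)
    th = rng.uniform(0, 2 * math.pi, total)
    x = cells["x_centroid"].to_numpy()[cell_rep] + rad * np.cos(th)
    y = cells["y_centroid"].to_numpy()[cell_rep] + rad * np.sin(th)

    # quality values: mixture with a stated fraction below 20
    low = rng.uniform(size=total) < config.low_qv_rate
    qv = np.where(low, rng.uniform(5.0, 20.0, total), rng.uniform(20.0, 45.0, total))

    # blank probes replace the gene call at the stated rate
    if config.blank_probes and config.blank_rate > 0:
        is_blank = rng.uniform(size=total) < config.blank_rate
        blank_names = rng.choice(np.asarray(config.blank_probes, dtype=object), is_blank.sum())
        feature = feature.copy()
        feature[is_blank] = blank_names

    cell_ids = cells["cell_id"].to_numpy(dtype=object)[cell_rep]

    # contamination: reassign a fraction of cytoplasmic transcripts to the
    # spatially nearest other cell
    if config.misassignment_rate > 0 and n_cells > 1:
        from scipy.spatial import cKDTree

        cand = np.flatnonzero(~in_nucleus & (rng.uniform(size=total) < config.misassignment_rate))
        if cand.size:
            tree = cKDTree(cells[["x_centroid", "y_centroid"]].to_numpy())
            _, nn = tree.query(np.column_stack([x[cand], y[cand]]), k=2)
            own = cell_rep[cand]
            swap = np.where(nn[:, 0] == own, nn[:, 1], nn[:, 0])
            cell_ids[cand] = cells["cell_id"].to_numpy(dtype=object)[swap]
            in_nucleus[cand] = False

    # a fraction of transcripts are never assigned to any cell
    unassigned = rng.uniform(size=total) < config.unassigned_rate
    cell_ids[unassigned] = None
    in_nucleus = in_nucleus & ~unassigned

    return pd.DataFrame(
        {
            "x_location": x,
            "y_location": y,
            "feature_name": feature,
            "qv": qv,
            "cell_id": cell_ids,
            "overlaps_nucleus": in_nucleus.astype(int),
            "sample_id": cells["sample_id"].to_numpy(dtype=object)[cell_rep],
        }
    )


def _nucleus_areas(rng, n, config):
    # lognormal around π r², clipped to stay biological
    base = math.pi * config.nucleus_radius_um**2
    return np.clip(base * rng.lognormal(0.0, 0.25, n), 3.0, 120.0)


def _sample_types(rng, mix: dict[str, float], n: int) -> np.ndarray:
    types = np.asarray(list(mix.keys()), dtype=object)
    p = np.asarray(list(mix.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(types, size=n, p=p)


def generate_tissue(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate transcript and cell tables plus ground truth for all samples.

    Deterministic given ``config.seed``: the same config yields byte-identical
    tables.  Each sample is an independent circular core whose coordinate
    origin is offset so samples never share coordinates.
    """
    rng = np.random.default_rng(config.seed)
    dyn = default_dynamic_genes(rng)
    gene_index = {g: i for i, g in enumerate(config.gene_panel)}

    all_cells, all_tx, lumens = [], [], []
    severity_records: list[tuple[str, float]] = []
    lumen_counter = 0
    offset = 0.0
    lay = config.layout
    R = config.core_radius_um

    for si in range(config.n_samples):
        sample_id = f"S{si + 1:02d}"
        if config.sample_severity_ranges is not None:
            sev_lo, sev_hi = config.sample_severity_ranges[si % len(config.sample_severity_ranges)]
        else:
            sev_lo, sev_hi = config.severity_range
        bg_remodeled = sev_lo >= 0.5
        # Structure list with halos.  Halos mimic the contiguous tissue
        # context each structure sits in — fibrotic remodeling around
        # remodeled airspaces, peribronchial tissue around airways,
        # perivascular adventitia around vessels — so niches form contiguous
        # regions rather than thin annuli floating in background.
        structs: list[dict] = []
        for _ in range(lay.n_alveoli):
            # endpoint severities: discrete homeostatic vs remodeled programs
            # keep planted niche labels recoverable; the severity continuum
            # lives in generate_remodeling_gradient
            s = float(sev_hi) if rng.uniform() < 0.5 else float(sev_lo)
            remodeled = s >= 0.5
            structs.append(
                dict(
                    kind="alveolus",
                    r_in=rng.uniform(*lay.alveolus_lumen_radius),
                    wall=rng.uniform(*lay.alveolus_wall),
                    # a halo is needed only when the airspace program differs
                    # from the surrounding parenchyma
                    halo=lay.remodeled_halo if remodeled != bg_remodeled else 0.0,
                    severity=s,
                    niche="remodeled_alveolar" if remodeled else "alveolar",
                )
            )
        for _ in range(lay.n_airways):
            structs.append(
                dict(kind="airway", r_in=rng.uniform(*lay.airway_lumen_radius),
                     wall=rng.uniform(*lay.airway_wall), halo=lay.airway_halo,
                     severity=None, niche="airway")
            )
        for _ in range(lay.n_vessels):
            structs.append(
                dict(kind="vessel", r_in=rng.uniform(*lay.vessel_lumen_radius),
                     wall=rng.uniform(*lay.vessel_wall), halo=lay.vessel_halo,
                     severity=None, niche="vascular")
            )
        for _ in range(lay.n_fibrotic):
            structs.append(
                dict(kind="fibrotic", r_in=0.0, wall=rng.uniform(*lay.fibrotic_radius),
                     halo=0.0, severity=None, niche="fibrotic")
            )

        specs = [(st["kind"], st["r_in"] + st["wall"] + st["halo"]) for st in structs]
        placed = _place_discs(rng, specs, R)

        cells_x, cells_y, cells_type, cells_niche, cells_sev = [], [], [], [], []
        sample_lumens: list[PlantedLumen] = []

        for st, (kind, x0, y0, r_tot) in zip(structs, placed):
            r_in, wall, halo, s, niche = (
                st["r_in"], st["wall"], st["halo"], st["severity"], st["niche"]
            )
            if kind == "fibrotic":
                xs, ys = _disc_points(rng, x0, y0, wall, lay.wall_cell_density)
                mix = FIBROTIC_MIX
            else:
                # wall + halo form one contiguous region of the same program
                xs, ys = _annulus_points(rng, x0, y0, r_in, r_tot, lay.wall_cell_density)
                if kind == "alveolus":
                    mix = _severity_mixture(s)
                elif kind == "airway":
                    mix = AIRWAY_MIX
                else:
                    mix = VESSEL_MIX
                lumen_counter += 1
                has_mac = False
                if kind == "alveolus" and rng.uniform() < lay.macrophage_lumen_fraction:
                    has_mac = True
                    mx, my = _disc_points(rng, x0, y0, r_in * 0.8, lay.macrophage_lumen_density)
                    mtypes = _sample_types(rng, LUMEN_MACROPHAGE_MIX, len(mx))
                    cells_x.append(mx + offset)
                    cells_y.append(my)
                    cells_type.append(mtypes)
                    cells_niche.append(np.full(len(mx), "airspace_macrophage", dtype=object))
                    cells_sev.append(np.full(len(mx), np.nan))
                sample_lumens.append(
                    PlantedLumen(
                        lumen_id=lumen_counter,
                        sample_id=sample_id,
                        kind=kind,
                        center=(x0 + offset, y0),
                        radius=r_in,
                        wall=wall,
                        severity=s,
                        has_macrophages=has_mac,
                    )
                )
            types = _sample_types(rng, mix, len(xs))
            cells_x.append(xs + offset)
            cells_y.append(ys)
            cells_type.append(types)
            cells_niche.append(np.full(len(xs), niche, dtype=object))
            cells_sev.append(np.full(len(xs), np.nan if s is None else s))

        # background: homeostatic alveolar parenchyma filling the core
        # (the distal lung between structures is alveolar septa, not empty
        # connective tissue), rejecting structure interiors
        n_bg = rng.poisson(math.pi * R**2 * lay.interstitial_cell_density)
        ang = rng.uniform(0, 2 * math.pi, n_bg)
        rad = R * np.sqrt(rng.uniform(size=n_bg))
        bx, by = R + rad * np.cos(ang), R + rad * np.sin(ang)
        keep = np.ones(n_bg, dtype=bool)
        for kind, x0, y0, r_tot in placed:
            keep &= (bx - x0) ** 2 + (by - y0) ** 2 > (r_tot + 2.0) ** 2
        bx, by = bx[keep], by[keep]
        cells_x.append(bx + offset)
        cells_y.append(by)
        cells_type.append(_sample_types(rng, _severity_mixture(float(sev_lo)), len(bx)))
        bg_niche = "alveolar" if sev_lo < 0.5 else "remodeled_alveolar"
        cells_niche.append(np.full(len(bx), bg_niche, dtype=object))
        cells_sev.append(np.full(len(bx), float(sev_lo)))

        x = np.concatenate(cells_x)
        y = np.concatenate(cells_y)
        ctype = np.concatenate(cells_type)
        niche = np.concatenate(cells_niche)
        sev = np.concatenate(cells_sev)
        n = len(x)
        cells = pd.DataFrame(
            {
                "cell_id": [f"{sample_id}_c{i:06d}" for i in range(n)],
                "x_centroid": x,
                "y_centroid": y,
                "nucleus_area": _nucleus_areas(rng, n, config),
                "sample_id": sample_id,
                "cell_type": ctype,
                "niche_label": niche,
                "severity": sev,
            }
        )

        # expression weights per cell: type profile, severity-modulated,
        # blended with the niche molecular program
        W = np.vstack([config.cell_type_profiles[t] for t in ctype])
        W = _blend_niche_programs(W, niche, sev, gene_index, config.niche_program_weight)
        graded = np.isfinite(sev)
        if graded.any():
            mult = np.ones((graded.sum(), len(config.gene_panel)))
            svals = sev[graded]
            for g, info in dyn.items():
                gi = gene_index[g]
                mult[:, gi] = [_dynamic_multiplier(info, s) for s in svals]
            Wg = W[graded] * mult
            Wg /= Wg.sum(axis=1, keepdims=True)
            W[graded] = Wg

        tx = _emit_transcripts(rng, config, cells, W)
        all_cells.append(cells)
        all_tx.append(tx)
        lumens.extend(sample_lumens)
        severity_records.extend((sample_id, s) for s in sev if np.isfinite(s))
        offset += 2 * R + 500.0  # samples never share coordinates

    cells = pd.concat(all_cells, ignore_index=True)
    tx = pd.concat(all_tx, ignore_index=True)
    truth = GroundTruth(
        cell_type=cells.set_index("cell_id")["cell_type"],
        niche_label=cells.set_index("cell_id")["niche_label"],
        lumens=lumens,
        severity=cells.set_index("cell_id")["severity"],
        dynamic_genes=dyn,
    )
    cells = cells.drop(columns=["cell_type", "niche_label", "severity"]).assign(
        cell_type=truth.cell_type.to_numpy()
    )
    return tx, cells, truth


def generate_remodeling_gradient(
    config: SyntheticConfig, n_airspaces: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Grid of alveolar airspaces spanning the full severity range.

    Severities are drawn uniformly over ``config.severity_range``; wall
    composition interpolates the homeostatic → remodeled mixtures and
    severity-dynamic genes follow their planted curve families with
    negative-binomial noise.  Geometry is a regular grid (one annulus per
    airspace) so the planted lumens are trivially separable; truth records
    the airspace id of every cell.
    """
    if n_airspaces < 30:
        raise ValueError(
            "n_airspaces must be ≥ 30: smaller gradients would be emptied by the "
            "downstream inclusion filters of the association analysis"
        )
    rng = np.random.default_rng(config.seed)
    dyn = default_dynamic_genes(rng)
    gene_index = {g: i for i, g in enumerate(config.gene_panel)}
    lay = config.layout

    r_in = float(np.mean(lay.alveolus_lumen_radius))
    wall = float(np.mean(lay.alveolus_wall))
    pitch = 2 * (r_in + wall) + 40.0
    ncol = int(math.ceil(math.sqrt(n_airspaces)))

    svals = rng.uniform(*config.severity_range, n_airspaces)
    rows = []
    lumens = []
    sample_id = "G01"
    for i in range(n_airspaces):
        cx = (i % ncol + 0.5) * pitch
        cy = (i // ncol + 0.5) * pitch
        s = float(svals[i])
        xs, ys = _annulus_points(rng, cx, cy, r_in, r_in + wall, lay.wall_cell_density)
        types = _sample_types(rng, _severity_mixture(s), len(xs))
        lumens.append(
            PlantedLumen(
                lumen_id=i + 1,
                sample_id=sample_id,
                kind="alveolus",
                center=(cx, cy),
                radius=r_in,
                wall=wall,
                severity=s,
            )
        )
        rows.append(
            pd.DataFrame(
                {
                    "x_centroid": xs,
                    "y_centroid": ys,
                    "cell_type": types,
                    "severity": s,
                    "lumen_id": i + 1,
                }
            )
        )
    cells = pd.concat(rows, ignore_index=True)
    n = len(cells)
    cells.insert(0, "cell_id", [f"{sample_id}_c{i:06d}" for i in range(n)])
    cells["nucleus_area"] = _nucleus_areas(rng, n, config)
    cells["sample_id"] = sample_id

    W = np.vstack([config.cell_type_profiles[t] for t in cells["cell_type"]])
    W = _blend_niche_programs(
        W,
        np.full(n, "alveolar", dtype=object),
        cells["severity"].to_numpy(),
        gene_index,
        config.niche_program_weight,
    )
    mult = np.ones((n, len(config.gene_panel)))
    for g, info in dyn.items():
        gi = gene_index[g]
        mult[:, gi] = [_dynamic_multiplier(info, s) for s in cells["severity"]]
    W = W * mult
    W /= W.sum(axis=1, keepdims=True)

    tx = _emit_transcripts(rng, config, cells, W)
    idx = cells.set_index("cell_id")
    truth = GroundTruth(
        cell_type=idx["cell_type"],
        niche_label=pd.Series("alveolar", index=idx.index, name="niche_label"),
        lumens=lumens,
        severity=idx["severity"],
        dynamic_genes=dyn,
        cell_lumen_id=idx["lumen_id"],
    )
    cells = cells.drop(columns=["severity", "lumen_id"])
    return tx, cells, truth


def simulate_group_compositions(
    seed: int,
    n_per_group: tuple[int, ...] = (6, 9, 9),
    n_types: int = 15,
    fold_change: float = 1.0,
    shifted_type: int = 0,
    concentration: float = 150.0,
    cells_per_sample: int = 20000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample cell-type count tables for composition testing.

    Emulates the disease-group design (unaffected / less fibrotic / more
    fibrotic): per-sample compositions are Dirichlet-distributed around a
    group mean (``concentration`` controls biological between-sample
    variability) and counts are multinomial.  ``fold_change`` multiplies the
    mean proportion of ``shifted_type`` in the two disease groups.
    Returns (counts table, group labels).
    """
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(n_types) * 5)
    rows, groups = [], []
    names = ["unaffected", "LF", "MF"]
    for gi, ng in enumerate(n_per_group):
        alpha = base.copy()
        if fold_change != 1.0 and gi > 0:
            alpha[shifted_type] *= fold_change
        alpha = alpha / alpha.sum()
        for _ in range(ng):
            pvec = rng.dirichlet(alpha * concentration)
            rows.append(rng.multinomial(cells_per_sample, pvec))
            groups.append(names[gi % len(names)])
    counts = pd.DataFrame(rows, columns=[f"type_{i:02d}" for i in range(n_types)])
    return counts, pd.Series(groups, index=counts.index)


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------


def write_tables(
    outdir: str | Path,
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    truth: GroundTruth | None = None,
    parquet: bool = True,
) -> None:
    """Write Xenium-style CSV (and Parquet) tables plus ground-truth JSON/GeoJSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts.to_csv(outdir / "transcripts.csv", index=False)
    cells.to_csv(outdir / "cells.csv", index=False)
    if parquet:
        transcripts.to_parquet(outdir / "transcripts.parquet", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "cell_type": truth.cell_type.to_dict(),
                    "niche_label": truth.niche_label.to_dict(),
                    "severity": {k: v for k, v in truth.severity.items() if np.isfinite(v)},
                    "dynamic_genes": truth.dynamic_genes,
                },
                indent=1,
            )
        )
        features = [
            {
                "type": "Feature",
                "properties": {
                    "lumen_id": p.lumen_id,
                    "sample_id": p.sample_id,
                    "kind": p.kind,
                    "severity": p.severity,
                },
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in p.polygon_coords()]],
                },
            }
            for p in truth.lumens
        ]
        (outdir / "truth_lumens.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
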