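# airscape

Spatial niche discovery and airspace-remodeling trajectory analysis for
imaging-based spatial transcriptomics of fibrotic lung.

Pulmonary fibrosis (PF) destroys the distal lung patchily: severely
remodeled tissue sits next to nearly normal alveoli in the same section.
Imaging-based spatial transcriptomics (e.g. 10x Xenium) measures hundreds of
genes per individual transcript at sub-cellular resolution, which makes it
possible to ask *where* disease-emergent cell states live and in what order
alveoli fall apart. `airscape` implements a complete analysis chain for
such data, aimed at computational biologists working with per-transcript
tables (x, y, gene, quality value `qv`, cell assignment, nucleus flag):

- **QC and ingest** — drop `qv < 20` and blank-probe transcripts, build the
  nuclei-restricted cell × gene matrix, filter cells (≥ 12 nuclear
  transcripts over ≥ 10 genes, ≤ 5% blanks, nucleus area 6–80 μm²),
  normalize, select principal components by the 90%-cumulative /
  0.05%-increment rule.
- **Cell-based niches** — k-means over each cell's 25-nearest-neighbor
  cell-type composition.
- **Transcript-based (cell-agnostic) niches** — spatial transcript graph
  (edges < 3 μm), two-hop mean-aggregator embedding trained by link
  prediction (GraphSAGE-style, dimension 50, fanout 20/10), Gaussian-mixture
  clustering of the embeddings, hexagonal-bin majority maps (width 5 μm,
  ≥ 10 transcripts/bin), nearest-bin cell assignment. No cell segmentation
  information enters this route.
- **Airspace (lumen) segmentation** — rasterize non-immune transcripts,
  morphological denoising, alpha-shape tissue boundary, label the enclosed
  negative space, attach cells within a 10 μm wall cutoff, then isolate
  putatively alveolar airspaces (25–500 cells, nucleus span ≥ 125 μm,
  composition triage, < 20% airway-niche membership).
- **Pseudotime** — PCA on airspace cell-type proportions (3 PCs), GMM
  (k = 5), MST over cluster centroids, iterated principal-curve smoothing;
  pseudotime t is arc length of each airspace's projection, oriented from
  the most homeostatic cluster: log μ = s(t) + log N along the curve.
- **Association statistics** — negative-binomial GAMs of aggregated counts
  on s(t) with the member-cell count as offset (cubic regression splines, 5
  knots, likelihood-ratio test, BH FDR), a cell-type-level variant
  log μ = s(t) + Σᵢ s(pᵢ) + log N controlling for composition,
  sliding-window peak ordering and Ward clustering of fitted patterns.
- **Composition statistics** — logit-proportion ANOVA across disease
  groups, regressions on semiquantitative pathology scores (0–3 grades
  summed per sample, ×0.36 for 5 mm cores), niche representative genes with
  one-vs-rest contrasts, and voom-style pseudobulk differential expression
  across annotated pathology features.

Everything runs against a bundled synthetic tissue generator
(`airscape.synthdata`) that emulates Xenium-like lung cores with planted
cell types, niches, lumens, a remodeling-severity gradient and
severity-dynamic genes, so the full pipeline is testable without any
download. See `docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables under `results/`. For example:

```bash
python analysis/06_trajectory.py 0
```

prints (seed 0):

```
composition PCA, explained variance of first 3 PCs: 0.72 0.05 0.04
pseudotime vs planted severity: Spearman |rho| = 0.960 (10 principal-curve iterations, start cluster 1)
```

— the first principal component carries most of the compositional gradient,
and the inferred airspace ordering almost perfectly recovers the planted
remodeling severity. Similarly, `analysis/07_associations.py 0` reports

```
flat genes significant at FDR<0.01: 0/10
monotone genes significant at FDR<0.01: 10/10
unimodal genes significant at FDR<0.01: 5/5
cell types associated with pseudotime: 13/14
```

i.e. every planted severity-dynamic gene is detected along the inferred
pseudotime while none of the flat controls is, and
`analysis/05_airspaces.py 0` reports perfect recovery of the planted
alveoli through the segmentation + filter cascade
(`sensitivity 1.00, precision 1.00`).

## Layout

```
src/airscape/       library: synthdata, qc, histology, niche_cells,
                    niche_transcripts, lumens, trajectory, association,
                    compstats
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. end-to-end planted-truth checks
scripts/acceptance.py
docs/methods.md     models, parameter choices, limitations
```
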