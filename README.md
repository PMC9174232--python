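# sclrcomm

Weighted gene co-expression modules, ligand–receptor (LR) communication
maps, trajectory dynamics and biomarker ranking for single-cell
expression data — with a synthetic-data generator that plants every
structure the pipeline is supposed to recover, so each analysis step can
be validated against a known ground truth.

The package implements the full analysis chain often used to study
intercellular signalling in tissue (e.g. fibroblast–cardiomyocyte
crosstalk in the failing heart):

1. **QC / preprocessing** — cell and gene filtering, `log2(x+1)`
   transform, rank-sum differential expression with exact small-sample
   p-values and Benjamini–Hochberg correction.
2. **Signed co-expression network** — soft-thresholded signed adjacency
   `((1+cor)/2)^β`, topological overlap matrix (TOM), automatic power
   selection by scale-free fit, and module detection by an adaptive
   top-down cut of the average-linkage dendrogram. Module eigengenes
   (first principal component) summarise module activity per cell.
3. **Cell–cell communication** — modules are annotated to cell types by
   marker-gene overlap; every database LR pair whose ligand and receptor
   fall into annotated modules becomes a directed cell-type interaction
   edge. Cell types are ranked by interaction degree, and gene sets are
   annotated by hypergeometric enrichment.
4. **Trajectories** — deterministic classical-MDS embedding,
   shared-nearest-neighbour graph clustering, minimum-spanning-tree
   lineages over cluster centroids, arc-length pseudotime, and smoothed
   module-eigengene dynamics with a permutation test for direction.
5. **Classification** — random-forest permutation importance (mean
   decrease in accuracy) of module eigengenes for a cell-level label,
   with a maxT permutation null for feature selection, plus
   cross-species module overlap via hypergeometric matching.
6. **Biomarker screening** — Mann–Whitney AUC, exact ROC curves, DeLong
   and stratified-bootstrap paired AUC comparison, and a per-protein
   screen that dissociates *diagnosis* markers from *severity* markers.

Everything is deterministic for a fixed seed, down to byte-identical
output files.

## Quick start

```python
from sclrcomm import network as net, preprocess as pp, synthetic as syn

cfg = syn.SyntheticConfig(
    n_genes=500, n_cells=200,
    modules=[syn.ModuleSpec(40) for _ in range(5)],
    cell_types=[
        syn.CellTypeSpec("A", 100, active_modules=("M1", "M3", "M5")),
        syn.CellTypeSpec("B", 100, active_modules=("M2", "M4")),
    ],
    noise_sd=0.3, seed=0,
)
X, truth = syn.generate_expression(cfg)
X = pp.log_transform(X)

cor = net.pearson_correlation(X)
tom = net.topological_overlap(net.signed_adjacency(cor, beta=6))
modules = net.detect_modules(tom, expression=X)
eigengenes = net.module_eigengenes(X, modules.assignment)
```

`truth` carries the planted gene→module map, per-cell module
activities, marker genes and LR pairs, so recovered structure can be
scored directly.

## Worked example

`examples/demo_config.yaml` simulates a heart-like dataset — 400 genes
× 240 cells, four cell types (CM, EC, FB, MP) of 60 cells each with 4
markers apiece, six planted modules (M1–M4 driven by one cell type
each, M5/M6 following a two-branch trajectory), six planted LR pairs
(FB→CM ×3, FB→EC ×2, EC→CM ×1) and a 90-sample plasma proteome — then
runs the full pipeline on it:

```bash
sclrcomm run --config examples/demo_config.yaml --out demo_out
```

This takes a few seconds and writes 18 files plus a manifest. What the
run recovers (seed 11, as configured):

- **Modules** (`module_assignment.tsv`): six modules of sizes
  39/39/39/39/30/30 — each planted module recovered intact, with the
  four cell-type-driven modules additionally absorbing their cell
  type's 4 marker genes; the remaining 184 background genes stay
  unassigned.
- **Interactions** (`interaction_counts.tsv`, `celltype_ranking.tsv`):
  the count matrix equals the planted truth exactly (FB→CM 3, FB→EC 2,
  EC→CM 1, all decoy pairs rejected), and FB tops the degree ranking
  (FB 5, CM 4, EC 3, MP 0).
- **Trajectory** (`dynamics.tsv`): on the lineage tracking the planted
  branch, M5 is called `increasing` (endpoint shift +0.92, permutation
  p ≈ 0.010) and M6 `decreasing` (−0.85, p ≈ 0.005); both are
  `non-monotone` on lineages that only reflect cell-type structure.
- **Classification** (`importance.tsv`): the two trajectory modules
  dominate the condition label — M5 first (mean decrease in accuracy
  0.29), M6 second (0.11), all other modules ≈ 0.
- **Biomarker screen** (`biomarker_screen.tsv`): the planted
  diagnosis-strong protein P_DIAG tops the diagnosis AUC (0.95 vs 0.53
  severity), the severity-strong P_SEV tops the severity AUC (0.99 vs
  0.81 diagnosis), and P_NULL sits near chance — the two tasks
  dissociate as planted.

Re-running the command reproduces every output byte for byte
(`manifest.json` records SHA-256 checksums).

The same stages are available as individual subcommands
(`sclrcomm simulate / qc / de / network / communicate / trajectories /
screen`); see `sclrcomm --help`.

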