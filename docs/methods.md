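# Methods

This note documents the statistical models, algorithms and parameter
defaults implemented in `sclrcomm`, and the scope of the synthetic
generator used to validate them.

## Synthetic data model

Expression is generated in log space and exponentiated:

```
x_gc = max(exp(b_g + Σ_m w_gm a_mc + s·1[g marker of type(c)] + ε_gc) − 1, 0)
```

- `b_g ~ N(baseline_mean=2, baseline_sd=0.3)` — per-gene baseline.
- Each planted module `m` has a latent activity `a_mc` per cell:
  `N(0, activity_sd)` plus `active_shift=2` for cells of a type in
  which the module is active. Member genes load on it with
  `w_gm ~ U(0.8, 1.2)`; non-members have `w_gm = 0`.
- Marker genes are background genes shifted by `marker_shift=2` in
  their cell type only.
- `ε_gc ~ N(0, noise_sd)`; optional dropout zeroes entries i.i.d.

In trajectory datasets the activities of designated modules are
deterministic in a planted pseudotime `t ~ U(0,1)`:
`a = ±slope·(t−½)` for up/down modules; with two lineages both branches
share the programme up to `branch_point`, after which the up-programme
continues only on lineage 1 and the down-programme only on lineage 2.
At `noise_sd = 0` trajectory-module expression is an exact monotone
function of pseudotime, which is what makes exact recovery testable.

The proteome generator is simpler: `baseline + group shift + N(0, σ)`
per protein and sample, with arbitrary group structure.

Scope: the generator emulates the *structures the pipeline claims to
recover* — co-expression modules, cell-type-restricted activity,
marker genes, planted ligand–receptor pairs, monotone trajectory
programmes, group-shifted proteins. It does not emulate count noise (no
negative binomial), library-size variation, batch effects or doublets;
analyses are validated on the log scale the pipeline actually operates
on (`log2(x+1)` after QC).

## Preprocessing

- Cell filter: strictly more than `min_genes` detected (> 0) genes.
- Gene filter: value ≥ `min_value` in ≥ `min_cells` cells.
- Transform: `log2(x+1)`.
- Differential expression: two-sided Wilcoxon rank-sum per gene, exact
  null for small groups without ties (the fully separated 3-vs-3 case
  gives p = 2/C(6,3) = 0.1 exactly), normal approximation with tie
  correction otherwise; Benjamini–Hochberg adjustment; significance at
  `adjusted_p < alpha` and `|log2 fold change| > lfc` (defaults 0.05,
  0.25).

## Signed network

- Correlation: Pearson across cells. Genes whose standard deviation is
  ≤ `1e-10 × max(|x|, 1)` are treated as constant and their
  correlations set to 0 — a *relative* tolerance, because exp/log
  round-trips leave ~1e-16 jitter on genes that are constant by
  construction, and correlations of pure rounding noise are meaningless
  (often exactly ±1).
- Adjacency: `a_ij = ((1 + cor_ij)/2)^β` (signed: anti-correlated
  pairs get near-zero weight).
- Topological overlap (TOM):
  `t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `l_ij = Σ_{u≠i,j} a_iu a_uj` and `k_i` the off-diagonal connectivity,
  computed in matrix form; equality with the literal triple sum is
  tested to 1e-12.
- Soft threshold: for each power 1–20, connectivity is binned into 10
  log-spaced bins and the signed R² of `log10 p(k)` vs `log10 k`
  (sign-flipped when the slope is positive) is recorded; the chosen β
  is the smallest power with R² ≥ `r2_target = 0.85`, or the argmax if
  none reaches it.

## Module detection

Clustering is average linkage on `1 − TOM`. Instead of a single global
cut height, the dendrogram is traversed top-down and a branch is
accepted as a module when it is **coherent** and **not splittable**:

- *Coherent*: mean internal TOM > `COHERENCE_RATIO = 2.0` × mean TOM
  to the rest of the network. Random gene sets sit near ratio 1, so
  this dissolves noise branches entirely (pure-noise inputs stay almost
  fully unassigned); the full gene set is never coherent by definition,
  so the degenerate "everything is one module" cut cannot be accepted.
- *Splittable*: both children (each ≥ 2 genes) have internal TOM >
  `SPLIT_RATIO = 1.3` × the cross-TOM between them. `SPLIT_RATIO` is
  deliberately weaker than `COHERENCE_RATIO`: two genuine modules that
  share a driver (e.g. both active in the same cell type) can have
  cross-TOM as high as half their internal TOM and must still be split
  apart, while the two halves of a single module sit at ratio ≈ 1.
  Average linkage grows modules by chaining in single leaves, so a node
  with one leaf child is split only if the non-leaf subtree separates
  from that leaf by the same criterion — otherwise accepting the node
  keeps the leaf in its module.

Accepted branches of ≥ `min_size = 30` genes become module cores;
smaller coherent branches are merged wholesale into the core with the
closest TOM centroid (an undersized module never survives on its own).
Remaining genes are assigned by module membership when expression is
available: a leftover joins the module whose eigengene it most
positively correlates with, provided that correlation is significant
under a t-test at family level `LEFTOVER_KME_ALPHA = 0.01`, Bonferroni
corrected over all leftover × module tests. A significance rule is used
instead of a magnitude cutoff because genes coupled to a module's
driver through an indicator readout (cell-type markers) have attenuated
but genuine correlation, while an unrelated gene's correlation is pure
sampling noise (`|r| ~ n_cells^(-1/2)`) and never survives correction.
Without expression, a TOM-only fallback requires the gene's mean TOM to
the module to beat both the 95th percentile of its TOM to everything
outside that module and one third of the module's internal TOM. Genes
failing these rules stay `unassigned`. Constant genes are excluded
before clustering and forced to `unassigned`.

Modules are labelled `M1, M2, …` by decreasing size; when expression is
given, module pairs with eigengene correlation > `merge_cor = 0.75` are
merged afterwards.

- *Eigengene*: first principal component of the module's standardized
  expression, scaled to unit variance and oriented so the mean member
  correlation is positive.
- *Membership (kME)*: Pearson correlation of every gene with every
  eigengene; constant genes get 0 with a flag.

## Communication

Modules are annotated to the cell type whose (disjoint) marker set they
overlap most; ties and zero overlap leave a module unannotated. Every
ligand–receptor database pair whose ligand lies in a module annotated
`s` and receptor in a module annotated `t` contributes a directed edge
`s → t` (autocrine edges on the diagonal); pairs touching unassigned
genes or unannotated modules contribute nothing. Cell types are ranked
by total degree (in + out), ties broken by name. The 2D ligand–receptor
map is classical (Torgerson) MDS on `1 − cor` with sign-fixed axes.
Gene-set enrichment is the one-sided hypergeometric upper tail
`P(X ≥ k)` (equivalent to one-sided Fisher's exact) with BH adjustment,
and cross-species module matching applies the same test per module pair
through an injective ortholog map.

## Trajectories

Cells are embedded by classical MDS on Euclidean distances between
standardized profiles (deterministic; UMAP available optionally), then
clustered on a shared-nearest-neighbour graph (edge weight
`shared/(2k − shared)`) by greedy modularity maximization. A minimum
spanning tree over cluster centroids defines lineages as root-to-leaf
cluster paths; pseudotime is arc length along the piecewise-linear
centroid path after orthogonal projection, rescaled to [0, 1]. Module
dynamics along a lineage use a sliding-window mean (window =
`span = 0.3` of cells) of the eigengene on a 100-point grid; direction
is called from the endpoint difference against a cell-permutation null
(`increasing`/`decreasing` below α = 0.05, else `non-monotone`).
Eigengene pairs with correlation ≤ −0.3 are flagged mutually exclusive.

## Classification

Feature importance is mean decrease in accuracy: each of `n_trees`
decision trees is fit on a bootstrap sample and its out-of-bag (OOB)
accuracy is compared with the OOB accuracy after permuting one feature;
the importance is the mean drop over trees (a constant feature is
exactly 0). Feature selection against a label-permutation null uses the
maxT (Westfall–Young) correction: the null distribution is the
per-permutation *maximum* importance across features and the cutoff its
95% quantile, controlling the family-wise error rate across features.

## Biomarker analysis

AUC is the Mann–Whitney estimator (ties credited ½); the ROC curve
enumerates thresholds at unique score values, starts at (0,0), ends at
(1,1), and its trapezoid area equals the AUC to numerical precision.
Paired AUC comparison implements the DeLong placement-value test
(normal reference) and a stratified bootstrap (positives/negatives
resampled separately) as a secondary method. The screen reports one AUC
per protein for a *diagnosis* contrast and one for a *severity*
contrast so that markers strong at one task but not the other can be
dissociated.

## Determinism and numerics

All stochastic steps take explicit integer seeds and use
`numpy.random.default_rng`; derived seeds are drawn below 2³¹. Output
files use a fixed column order, `%.10g` floats and `\n` line endings,
so a rerun with the same config is byte-identical (the pipeline
manifest records SHA-256 checksums). MDS axis signs are fixed by making
the largest-magnitude coordinate positive; eigengene orientation by the
mean member correlation.

## Limitations

- The generator's noise model is Gaussian in log space; count-level
  properties (overdispersion, library size, batch) are out of scope.
- Module detection assumes the network contains *some* background: an
  input in which every gene belongs to one module has no "rest of
  network" against which coherence can be measured, and the descent
  will instead return the module's internal split structure.
- Lineage counting reflects the geometry of the embedding: strong
  discrete cell-type structure along a trajectory can introduce
  additional MST leaves (extra lineages) beyond the planted branches.
  The bundled demo shows this: the planted two-branch dynamics are
  recovered on the branch-tracking lineage, but cell-type clusters
  contribute further root-to-leaf paths.
- The TOM-only leftover fallback (no expression provided) is more
  permissive than the membership-significance rule; when expression is
  available the significance rule is always used.
- Greedy modularity clustering and MST lineages are deterministic but
  resolution-dependent; `k` and `resolution` matter near cluster-size
  boundaries.
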