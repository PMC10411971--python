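# Methods

`cardiocomm` reimplements, as a tested library, a comparative
single-cell analysis of inflammatory cells in regenerating zebrafish
hearts: macrophages and neutrophils sorted from cryoinjured ventricles
under a regenerative control condition (PBS) and a macrophage-delayed
condition (clodronate liposomes, CL), profiled uninjured and at 1, 3
and 7 days post cryoinjury (dpci). Because the raw sequencing data are
not part of the package, every stage is driven and validated by a
synthetic-data generator with planted ground truth.

## Synthetic data generator

Counts for gene *g* in cell *i* of cluster *c* are negative binomial
with mean `mu[g,c] * f[i]` and shared dispersion `phi`
(gamma–Poisson sampling, `r = 1/phi`); `f[i]` are log-normal
library-size factors. Defaults:

| parameter | default | meaning |
|---|---|---|
| `nb_dispersion` | 0.1 | shared NB dispersion across genes (single-cell scale) |
| `libsize_lognormal` | (0, 0.35) | log-normal (mu, sigma) of cell size factors |
| `n_cells_per_dataset` | 2000 | desk-scale; the study's 9–17k per library is reachable via config |
| `lr_high` | 50 | NB mean of a planted ligand/receptor in its sender/receiver |
| `damaged_cell_frac` | 0.02 | cells with mitochondrial UMI share raised to 0.35 |
| mito fraction | 0.08 | expected mitochondrial share of UMIs in intact cells |

Twelve inflammatory clusters are simulated (Mac1–Mac9, Neu1, Neu2 and
the hybrid MN) across seven datasets (UN, PBS1d/3d/7d, CL1d/3d/7d).
Cluster sizes are multinomial draws from per-dataset proportion
vectors in which the resident macrophage clusters Mac2/Mac3 expand
under PBS and collapse under CL while neutrophils resolve under PBS
and are retained under CL. Per-gene baseline means are log-normal
(median 0.45 counts/cell, sigma 1.4); each cluster gets a disjoint
block of 12 six-fold markers. The baseline median is chosen so a cell
carries ~1.2 UMIs per gene in the universe, which keeps the
complexity metric log10(genes)/log10(UMIs) above 0.8 for healthy
cells as in real 10x data; note that below ~600 genes the complexity
rule cannot be satisfied at all (it requires detected genes >
UMIs^0.8), so QC-bearing configurations use universes of at least 600
genes.

Planted truth: condition-enriched genes multiply the NB mean by
`2**log2fc` in one cluster under one condition; planted
ligand–receptor pairs use dedicated genes that are near-silent
(mean 0.05) everywhere except the stated sender (ligand) and receiver
(receptor) under the stated condition, where the mean is `lr_high`.
Output is bit-identical for a fixed (config, dataset): the RNG seed is
derived from the config seed and a CRC of the dataset id.

The generator does **not** emulate ambient RNA, doublets, batch
effects, read-level errors, or clustering uncertainty (cluster labels
are ground truth, not inferred). Passing tests therefore demonstrate
correct recovery of planted signal under idealized labels, not
robustness to upstream mis-clustering.

## Barcode quality control

Four rules, all strict inequalities, applied jointly: UMIs > 400,
detected genes > 200, log10(genes)/log10(UMIs) > 0.8, mitochondrial
UMI fraction < 0.23. Barcodes with fewer than two UMIs have an
undefined complexity ratio and fail that rule by definition; zero-UMI
barcodes are reported, never silently dropped. Mitochondrial genes are
identified by the `mt-` name prefix with an explicit-list override.

## Pseudobulk

`raw_mean[g,(c,d)]` is the plain mean count over the cells of cluster
*c* in dataset *d*; `raw_sum` the sum. The normalization sentence of
the source protocol names two quantities — total read counts and cell
numbers — and the package makes each enter exactly once: cell number
via the mean, library size via within-group scaling of summed counts
to counts-per-`scale` (default 1e6), so every normalized column sums
to `scale`. Upper-quartile factors for bulk samples are
`UQ_s / gmean(UQ)` with `UQ_s` the 75th percentile (linear
interpolation) of the sample's nonzero values; nonzero-only so
sparsity cannot collapse the quartile to zero.

Marker genes use a two-sided Wilcoxon rank-sum test of the cluster
against all other cells (a deliberate, documented stand-in for the
original hurdle-model test), restricted to genes detected in ≥25% of
the cluster's cells, Bonferroni-corrected over tested genes, retained
at adjusted p < 0.05 and ranked by average log2 fold change then
p-value. Constant genes are assigned p = 1.

## M–D differential expression

For each gene, `M = log2(x1'/x2')` and `D = |x1' - x2'|` on
normalized values with zeros replaced by `k = 0.5` (applied only to
zeros). Designs without within-condition replicates get simulated
technical replicates: multinomial subsamples of each library at
fraction `pnr = 0.2`, `nss = 5` replicates, with probabilities jittered
by ±`nv = 0.02` uniform noise. The noise distribution pools `(|M|, D)`
over all within-condition replicate pairs and all genes
(`n_genes * sum_cond C(n_rep, 2)` points). The differential
probability is

```
q = #{ (m, d) in noise : m <= |M| and d <= D } / |noise|
```

with non-strict comparisons so ties count toward the noise — a
conservative choice, made explicit because tie handling is not part of
the published description. Genes are called at q strictly above the
threshold: 0.99 for bulk contrasts, 0.8 by default for per-cluster
pseudobulk condition-enrichment screens (the stricter 0.99 remains
available; only the bulk threshold is printed in the source study).
`q` is jointly non-decreasing in `|M|` and `D`, invariant to noise
permutation, and swapping the contrast flips the sign of `M` while
preserving `D`.

Calibration and power are checked at bulk-realistic conditions: 2000
genes with log-normal means (median 500 counts, sigma 1.0 — the
per-gene depth of a 2000-gene slice of a 15–20M-read library) and
between-sample dispersion 0.02 (libraries pool three ventricles, so
residual biological CV ~14%). Under these conditions the null contrast
calls ≤0.1% of genes at q > 0.99 and planted 4-fold genes at NB mean
≥ 50 are recovered with sensitivity ~0.89. At much shallower depth or
single-cell-scale dispersion the technical-replicate null no longer
matches between-sample variability and both error rates degrade; the
method is a bulk/pseudobulk tool, not a per-cell test.

## Cluster composition

Per-dataset proportions, stacked time-course percentages, and the
condition contrast

```
log2_ratio = log2((n_a + pc)/(N_a + pc)) - log2((n_b + pc)/(N_b + pc))
```

with pseudocount `pc = 0.5` on counts (Haldane–Anscombe style) so
clusters that vanish under one condition — as the resident Mac2
cluster does under CL — stay finite. The log-difference form makes the
contrast exactly antisymmetric in floating point. Injured timepoints
(1, 3, 7 dpci) are pooled by default; a per-timepoint mode exists
because the original pooling is not recoverable from the text. The
ratio is reported descriptively (no significance test), matching the
source analysis.

## Ligand–receptor crosstalk

A human ligand→receptor pair table is ortholog-expanded to zebrafish
by the full Cartesian product of each side's ortholog sets (paralog
receptors are reported as distinct pairs in the source data, hence no
best-hit collapsing); pairs with an unmapped side are dropped and
counted. A small curated demo pair table and ortholog map ship with
the package; they illustrate the format and are not the full database.

A gene is *expressed* in a (cluster, dataset) group when its
normalized pseudobulk value is ≥ the group's upper quartile over
nonzero values (quantile and zero-handling are parameters; ties count
as expressed). Edges are enumerated for every database pair with the
ligand expressed in a sender and the receptor in a receiver;
macrophage→neutrophil and neutrophil→macrophage analyses run
separately, and autocrine edges are allowed when sender equals
receiver. Comparing two conditions at a matched timepoint (edge
identity excludes the dataset field) partitions the union into
PBS-only / CL-only / shared.

A caveat the synthetic recovery tests make explicit: a hard quantile
cutoff is unstable for genes sitting *at* the cutoff — between any two
estimates of the same group, a few marginal genes flip in or out of
the expressed set, so genes near the upper quartile can generate
spurious condition-specific edges. Planted-truth recovery is therefore
evaluated with decoy pairs that follow the generator's bimodal LR
model (constitutively shared or silent), where the call is
well-posed; for borderline-expression genes the condition-specific
label should be treated as a hypothesis, not a detection.

## Pipeline and problem sizes

`run_pipeline` executes simulate → QC → pseudobulk → DE → composition
→ crosstalk → evaluation from one `PipelineConfig` (YAML-loadable),
writes TSV/CSV/SIF/GraphML outputs plus a JSON manifest of SHA-256
hashes with relative paths, and is byte-identical for a fixed
(config, seed); each stage draws from its own seeded generator.
Per-cluster condition contrasts pool injured timepoints of each
condition's `raw_sum` and run the M–D caller with simulated
replicates. The evaluation stage compares DEG calls, the composition
contrast and condition-specific edges against the planted truth.

Default problem sizes — 1000 genes × 2000 cells × 7 datasets for the
pipeline, 2000-gene bulk pairs for M–D checks, 4000-cell two-dataset
runs for crosstalk recovery — are desk-scale choices that keep the
whole suite under a minute while leaving every statistical check
well-powered; the study-scale 9–17k cells per dataset is a config
change.

## Known limitations

* Cluster labels are taken as given; no integration/clustering is
  performed (the upstream Seurat steps are out of scope).
* The M–D noise model is the simulated-technical-replicate variant;
  the empirical-Bayes biological-replicate variant is not implemented.
* The demo LR database is illustrative, not exhaustive; results on
  real data require the full ortholog-mapped database.
* Expressed-set calls near the upper-quartile cutoff are threshold-
  sensitive (see above).
* Composition ratios carry no uncertainty estimate by default.
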