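# Methods

`tmekit` implements the downstream statistics used to analyze a
multi-sample, two-condition (tumor/normal) single-cell RNA-seq atlas of a
tumor microenvironment, together with a ground-truth simulator that makes
every stage testable without access to patient data. This note records the
models, the parameter choices that matter, and the places where the design
was genuinely open.

## Preprocessing

Cells are kept when they express more than 200 and fewer than 7,000 genes
("expressed" = UMI count > 0, the standard convention) and when their
mitochondrial UMI fraction (genes prefixed `MT-`, configurable) does not
exceed 10%. The boundary semantics are deliberate: a cell with exactly 200
expressed genes or exactly a 10% mitochondrial fraction survives; only
cells strictly outside the window are removed. QC is idempotent.

Counts are scaled to 10,000 per cell and log1p-transformed:
`x_gc = log(1 + 10^4 · n_gc / N_c)`. Variable genes are those whose mean of
`expm1(x)` lies in [0.05, 5] and whose dispersion (variance/mean of
`expm1(x)`) is at least 0.5 — the de-logged scale is the convention of the
droplet-pipeline lineage these thresholds come from, and is our reading of
"average expression" and "dispersion".

`regress_and_embed` residualizes each gene on per-cell covariates
(typically total UMI and mitochondrial fraction; optionally cell-cycle
scores computed with `gene_set_score`), z-scales per gene with values
clipped at ±10 (a standard cap that keeps outlier cells from dominating
the scaled matrix), and projects the cells on the top 20 principal
components. Cross-sample integration (CCA/Harmony and kin) is *not*
reimplemented: any externally computed embedding can be passed through,
which keeps the downstream clustering contract integration-agnostic.

## Two-round reclustering

Graph clustering is Leiden community detection (RB-configuration
modularity) on an unweighted k-nearest-neighbor graph (k = 20 by default;
neither the community algorithm nor k is dictated by the procedure itself,
so both are explicit config values). Resolution 0.4 is the default for a
first pass; reclustering within a cell type is usually explored at 0.4,
0.6 and 0.8, and the resolution is a recorded *user* choice — never
auto-selected, because the criterion (recovery of known subtypes) is
biological.

The second round removes variable genes whose expression variance is
driven by sample rather than by cell cluster. For each gene we fit the
additive two-way model `expression ~ sample + cluster` on per-cell
log-normalized values and compute per-factor sums of squares; genes with
`SS_sample / (SS_sample + SS_cluster) > 0.9` are dropped and the embedding
and clustering recomputed on the remainder.

The variance decomposition is **sequential (type I) with sample entered
first** by default. This is the one genuinely consequential numerical
choice in the module, so it is worth spelling out. When sample-driven
genes are strong, the *first-round* clustering tends to split cells by
sample before cell state; in the extreme, every cluster is a subset of one
sample and the cluster factor nests the sample factor. A decomposition
that adjusts each factor for the other (type II) then credits the shared
variance to cluster and assigns `SS_sample ≈ 0` — the filter goes blind in
exactly the regime it exists for (we observed sensitivity ~0 for planted
sample-driven genes under nested round-1 clusters). Entering sample first
credits the shared variance to sample, recovers the planted batch genes at
sensitivity ≥ 0.97 and specificity 1.0 in our simulations, and coincides
with type II on balanced crossed designs (asserted against a statsmodels
`anova_lm` oracle). Type II remains available via `ss_type="II"`. No
interaction term is fit: the filter statistic is defined from the two main
effects only. Constant genes get `sample_fraction = 0` and are kept.

Note the filter statistic's null behavior: for a gene with *no* structure
at all, `SS_sample/(SS_sample+SS_cluster)` is a ratio of independent
chi-square variables (Beta-distributed, e.g. Beta(3/2, 1) for 4 samples
and 3 clusters), so pure-noise genes exceed 0.9 with non-trivial
probability and are removed. That is acceptable — losing uninformative
genes costs nothing — but it means "fraction > 0.9" should not be read as
a calibrated test; it is a screening rule. Genes with genuine cluster
signal essentially never trip it.

Per-cell values are the ANOVA observations (a flag switches to
cluster × sample cell means); which the original procedure used is not
documented, and per-cell is the more direct reading.

**Cluster robustness.** Each of 30 repetitions samples 75% of cells
without replacement, reclusters them with identical parameters and
features, and records for each original cluster the largest fraction of
its sampled members assigned to a single resampled cluster; robustness is
the mean over repetitions. The matching rule ("largest overlap") is the
simplest consistent reading of "still clustered into a single cluster";
Jaccard-style matching would penalize resampled clusters that absorb
extra cells, which the verbal definition does not ask for. Repetitions in
which a cluster contributes no sampled cell are skipped for that cluster
(and logged). Robustness is invariant to cluster-label permutation.

## Signature scores

For a candidate gene and focal cluster, let `t` be the 25th percentile of
the gene's nonzero values within the focal cluster and `h_c` the fraction
of cells of cluster `c` with value > `t`. The **cluster specificity
score** is

    s_cluster = max(0, 1 − max_{c≠focal} h_c / h_focal).

The **cell-type specificity score** is the same construction across major
cell types with the detection threshold at the 5th percentile of the
gene's nonzero values over all cells. The exact algebraic form of these
scores is not uniquely pinned down by their verbal definition; the ratio
form above satisfies both stated boundary identities — exactly 1 for a
gene expressed only in the focal cluster, exactly 0 as soon as any single
competitor's fraction reaches the focal fraction — is bounded in [0, 1],
monotone in the focal fraction, and depends only on ranks relative to a
within-data quantile (hence invariant to monotone rescaling of the gene).
The competitor aggregation is the **maximum** (worst competitor), because
the zero boundary is stated against any single other cluster. The
quantile threshold is computed once in the focal cluster and applied to
all clusters. The combined score is the geometric mean
`sqrt(s_cluster · s_type)`; genes with combined ≥ 0.7 (inclusive — the
cutoff's strictness is unstated) are signature genes.

Candidates come from per-cluster differential expression. The DE test is
a two-sided Wilcoxon rank-sum with Benjamini-Hochberg correction — a
deliberate stand-in for a hurdle-model fit, since the substance lies in
the filter rule, which is applied exactly: expression percent > 10% (in at
least one group), fold change > 2, adjusted p < 0.05. Fold change is
`(mean expm1 + 1)/(mean expm1 + 1)` with pseudocount 1 to stay finite.

`gene_set_score` is the per-cell arithmetic mean of normalized expression
over a named set — the exhaustion panel (PDCD1, LAG3, TIGIT, HAVCR2,
CTLA4) ships as a constant; Treg, M1/M2 and similar signatures are
user-supplied files. Missing genes are always reported, and fewer than
50% coverage (configurable) is an error, never a silent drop.

## Cluster abundance

The number of cells sample `s` contributes to a cluster is modeled as
Poisson with the sample's total as exposure:
`log E[y_s] = β0 + β1·I(tumor_s) + log N_s`, fit by IRLS; `β1` is the log
rate ratio and its Wald z gives a two-sided p. Samples (not pooled
conditions) are the observation units, one fit per cluster. Overdispersion
is not modeled by default — matching a plain-Poisson fit — but a
quasi-Poisson scale flag exists; under the simulated null the Wald test is
calibrated (rejection rate ≈ 0.05 at α = 0.05). When one condition has
only zero counts for a cluster, 0.5 is added to that cluster's count in
every sample (flagged) so the Wald statistic stays finite. Raw p is the
primary output; BH-adjusted p is reported alongside since no correction
was part of the original per-cluster procedure.

## Dendrogram

Cluster profiles are mean normalized expression of the cell type's
variable genes (the post-ANOVA-filter set, consistent with the
reclustering features). Distance is `(1 − Pearson r)/2`. The tree is
average-linkage (UPGMA) by default — the construction itself was never
specified beyond the plotting package, and UPGMA is the conventional
choice for correlation distances — with neighbor joining behind a flag;
output is Newick.

## Ligand-receptor interactions

For a directed cluster pair A→B and a catalogued pair, the statistic is
the mean of the ligand's average expression in A and the receptor's in B;
a multi-subunit complex is represented by its minimum-mean subunit. Only
combinations where every ligand subunit is detected in **more than** 25%
of A cells and every receptor subunit in more than 25% of B cells are
tested (25.0% exactly is excluded). The null is 1,000 permutations of the
cluster labels over all cells jointly — one shared shuffle per permutation
for all pairs, so each permutation yields one coherent null landscape.
"As or more extreme" is implemented one-sided (≥): interactions are
enrichment claims. The empirical P is `(1 + #{perm ≥ obs})/(n_perm + 1)`;
the add-one rule keeps P > 0 with finite permutations, and the raw
proportion is available by flag for literal replication. The interaction
count matrix counts tested combinations with P below 0.05 (the upstream
convention; configurable, since the original count threshold is unstated)
per directed cluster pair.

## Bulk validation

TPM values are normalized gene-wise by the mean over normal samples
(genes with zero normal mean are excluded and reported); no log transform
is applied before or after — the literal reading of the procedure. Tumor
samples are ranked by mean normalized signature expression; the top and
bottom ⌊n/4⌋ form the high and low groups (the rounding rule is ours; the
original defines only "top/bottom 25%"), with ties broken by sample ID for
determinism and a constant average flagged as degenerate. The module emits
a survival-ready table (sample, signature average, group); Cox/KM fitting
is standard tooling and out of scope.

## Synthetic data

`simulate_counts` draws negative-binomial (gamma-Poisson) UMI counts —
the standard overdispersed model for droplet data; a Poisson-lognormal
would add nothing the downstream tests can detect — with log-mean
`log(baseline_g) + log2fc(g, cluster)·log 2 + batch(sample, g) +
log(libsize_c)`. Batch effects are Gaussian on the natural-log scale,
drawn once per (sample, gene) — exactly the additive structure the ANOVA
filter targets — with sd 0.3 by default (mild shared batch) and an
optional designated batch-gene subset with its own sd. Defaults: 4 samples
(2 tumor / 2 normal), 300 cells each, 500 genes of which 10 are `MT-`
prefixed carrying ~5% of counts, inverse-dispersion θ = 5
(var = μ + μ²/θ, UMI-typical), library sizes lognormal around 2,000 UMIs,
equal cluster proportions in both conditions (enrichment is planted
explicitly per experiment). Marker genes (default: ten per cluster at +2
log2) get their baseline pinned to an expected 0.3 counts/cell so planted
effects land at a realistic, detectable expression level. A single global
seed drives one generator stream; outputs are bit-reproducible.

`simulate_lr_table` assembles ligand-receptor pairs (optionally with
two-subunit receptor complexes) from the simulated gene pool and returns
the expression plan realizing them: +2 log2 global boost for all catalogue
genes (so they clear the 25% detection filter) and a further +2 log2 for
active triples in their sender/receiver clusters. `simulate_bulk` draws
lognormal TPM (median 10, σ = 1) and shifts the signature genes by a given
log2 effect in a 25% subset of tumor samples.

What the generator does **not** emulate: gene-gene correlation beyond
cluster/batch structure, doublets, ambient RNA, realistic gene-rank
expression distributions, or condition-dependent transcriptional states
within a cluster. Passing tests therefore demonstrate that the statistics
recover planted structure of the assumed form under realistic noise — not
that they are robust to every artifact of real droplet data.

## Problem sizes used in validation

The validation suites run at deliberately modest scale, chosen to exercise
the statistics without redundancy: calibration and recovery of the
abundance GLM use 100 (recovery) and 500 (null) replicates of 6+6 samples;
permutation-test calibration uses 400 tested combinations at 200
permutations and power uses 100 simulation runs; the two-round
reclustering benefit uses 20 simulations of 1,000 cells with a 100-gene
variable set containing 30% planted batch genes; robustness uses 30
resamplings of 120 cells. The whole suite completes in well under a
minute of compute per heavy test.

## Known limitations

- The specificity-score algebraic form is a faithful reconstruction from
  boundary behavior, not a transcription of a printed formula; alternative
  monotone forms would rank genes slightly differently in the interior of
  [0, 1].
- The rank-sum DE stand-in differs from hurdle-model inference for genes
  with strong detection-rate differences but similar nonzero means.
- The Poisson abundance model ignores biological overdispersion across
  samples; with few samples per condition the quasi-Poisson flag is
  advisable for real data.
- The sequential ANOVA default intentionally over-attributes
  sample/cluster-shared variance to sample; on strongly unbalanced designs
  where clusters legitimately differ in sample composition, it will remove
  more genes than type II would.
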