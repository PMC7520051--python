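# Methods

This note documents the models, statistics and numerical choices behind
`armnet`, and what the synthetic-data tests do and do not establish about
real tissue data.

## The synthetic cohort

`simulate_dataset` draws UMI counts from a gamma-Poisson model: gene *g* in
cell *i* has mean `lib_i · p_ig`, where `p_ig` is a per-cell normalized
expression profile and `lib_i` is a lognormal size factor (default mean
library 1,200 UMI, log-SD 0.35, matching the scale of nuclear droplet
data). Overdispersion uses a single gamma shape `1/φ` with `φ = 0.3`.
Profiles are built from a lognormal baseline over genes, multiplied by:

* **cell-type programs** — each of seven cortical types (oligodendrocytes
  36%, excitatory neurons 32%, astrocytes 12.8%, inhibitory neurons 10%,
  OPCs 5.6%, microglia 3.2%, endothelial 0.4%) elevates its program
  e^2.0-fold. A program is the type's canonical markers (CX3CR1/C1QB/CSF1R…
  for microglia, MBP/MOG/OLIG1… for oligodendrocytes, and so on) plus 25
  anonymous program genes: real cell types differ across hundreds of genes,
  and a handful of markers alone would make the types unseparable by any
  clustering — a property of the data, not the method.
* **microglial subtype programs** — homeostatic (CX3CR1…), motile (FGD4,
  ARHGAP15/24…), ARM (CD163, SPP1…) and dystrophic (FTL, FTH1…), each with
  15 extra program genes at e^1.5.
* **batch effects** — an `exp(N(0, 0.15))` factor per (gene, sample).
* **mitochondrial content** — `MT-`-prefixed genes absorb a per-cell
  Beta-distributed fraction of the library (mean 2.5%, below the 5% QC cap
  so ordinary nuclei survive).

**ARM membership** follows a logistic model. The subtype table's baseline
(ARM 77.5%) describes the reference condition — amyloid-positive,
tau-negative tissue from an *APOE* E3/E3, *TREM2* wild-type donor — and the
donor's condition adds log-odds shifts: −3.71 for A−T− tissue, log 0.101
for A+T+, log 0.528 per *APOE* E4 allele, log 0.509 for *TREM2* R47H. The
non-ARM mass is split between the other subtypes in proportion to their
baseline shares. The default 15-donor cohort (2 A−T−, 5 A+T−, 8 A+T+; four
R47H carriers; E4 alleles concentrated in the tau-positive group, with one
E3/E3 donor per pathology stratum so genotype comparisons can be matched)
thus reproduces, in expectation, the subpopulation shifts the analysis is
designed to detect. **Doublets** replace a configurable fraction (default
1%) of nuclei with the summed counts of two same-sample cells, reflecting
nuclei fusion within a homogenate.

What the generator does *not* emulate: transcriptome-wide correlation
structure beyond the planted programs, ambient RNA, empty droplets, or
spliced/unspliced structure. Tests passing on this cohort therefore verify
the *statistical machinery* — filters, estimators, calibration — not
biological discovery on tissue.

`fixture_small` is a deterministic 300-cell × 500-gene matrix with exactly
12 cells under the 200-gene floor, 5 over the fixture's documented
400-gene ceiling, 8 over the 5% mitochondrial cap (disjoint groups), 15
genes expressed in exactly 5 cells and 5 genes in exactly 12, so filter
counts can be asserted exactly.

## QC and preprocessing

"Expressed" means count > 0. The gene-count interval is closed
([200, 4,000] kept) and the mitochondrial cap strict (< 5%); cells with a
zero library have mito fraction 0. The gene filter (≥ 10 surviving cells)
runs once, after the cell filter, and is not iterated — re-running the cell
filter afterwards could remove more cells, and the single pass is the
documented behaviour.

Normalization scales each cell to 10,000 counts then applies natural
log1p; all-zero cells stay zero with a logged warning. HVG selection ranks
genes by dispersion (variance/mean of the de-logged values) z-scored within
20 quantile bins of log mean expression, so expression level does not
masquerade as variability; defaults are 2,000 genes for the full cohort and
5,000 for microglia re-clustering. Scaling standardizes HVG columns to zero
mean/unit variance within each sample (population SD; SD 0 ⇒ the column
stays 0; single-cell samples are centered only), clipping at ±10 SD to stop
single outlier nuclei from dominating PCA — clipping is configurable and
disabled in the tests that assert exact moments.

## Clustering and consensus annotation

The clustering backend is pluggable: Leiden (RB-configuration quality,
seeded) or Louvain (igraph multilevel) on an undirected kNN graph
(k = 15) built in a 50-component PCA of the scaled HVG matrix. These are
hard-assignment algorithms, so the per-cell assignment confidence
`max_prob` is 1.0. The resolution ladder is 0.1–0.8 in steps of 0.05
(15 values).

Each cluster is annotated with the cell type whose marker set has the
highest mean standardized expression (genes z-scored across cells; missing
markers ignored; exact ties leave the cluster unassigned). A nucleus is
labeled T only if its per-resolution labels equal T at ≥ R of the R
resolutions — relaxed to R−1 for endothelial cells and OPCs, which are rare
or similar to oligodendrocytes and merge with neighbours at the lowest
resolution. Unannotated nuclei are excluded downstream. The consensus
output depends only on vote counts, hence is invariant to resolution order.

**Microglia re-clustering** departs from the cohort-level pass in two
documented ways. First, scaling is global rather than per-sample: subtype
proportions differ across donors *by design* (that is the biology under
study), so standardizing within donors would subtract subtype signal along
with batch signal. Second, a single higher resolution (default 2.0) is
used: the kNN-graph backends need it before small contaminant clusters
separate from genuine subtypes, and their resolution scale is not
commensurate with the original embedding-based backend's 0.1–0.8 range.
Kept subclusters are named by their best-scoring subtype marker program.

**Contaminant flagging.** A subcluster is flagged when (a) its mean
standardized expression of some non-microglial marker set is both elevated
in absolute terms (score > 0.5) and > 2 SD above the other subclusters,
and (b) its mean detected-genes per cell exceeds the median of the
non-candidate subclusters — doublets carry roughly double the RNA. Flagging
every subcluster raises an error (mis-specified markers). The absolute
score condition matters: with only a handful of subclusters the
between-cluster SD is tiny and relative z-scores alone misfire on genuine
subtypes.

## Batch-mixing KL divergence

For each of N seeded query cells (sampled without replacement), the batch
composition `p` of its K nearest neighbours (Euclidean; the query itself
excluded — the region should describe the neighbourhood, not the query) is
compared with the global composition `q` by `Σ_b p_b log(p_b/q_b)` with
natural log and `0·log 0 = 0`. The divergence is 0 iff the region matches
the global mix and reaches `log B` for regions pure in one of B equally
sized batches. Medians decrease as K grows on well-mixed data, since larger
regions average toward the global composition.

## Differential expression

The Wilcoxon rank-sum test uses the normal approximation with tie
correction and a 0.5 continuity correction (identical to the asymptotic
two-sided Mann–Whitney convention, verified against an independent
implementation in the tests). Fold changes are computed on de-logged
normalized means with a 1e-9 pseudocount; the threshold is applied to
|log2FC| so both up- and down-regulated genes are reported, with direction
from the sign. BH correction runs across genes within each comparison.
Groups with fewer than 3 cells are skipped with a warning. ANOVA gene
selection ranks genes by one-way F-test p-value (constant genes get p = 1);
risk-gene matrices keep genes with non-zero expression in ≥ 20% of cells of
at least one group and z-score the group means across groups.

## Proportion statistics

The 2×2 table counts target/non-target cells in two conditions, pooling
cells across donors within a condition (matching proportion bar plots; a
stratified per-donor variant can be built from the same primitives). The
odds ratio is the raw cross-product `ad/bc` — exactly the OR implied by the
two row proportions — with a Woolf log-OR 95% CI (`±1.96·√(1/a+…+1/d)`),
switching to a Haldane +0.5 on all cells when any cell is zero, and a
two-sided Fisher exact p-value (sum of hypergeometric probabilities no
larger than the observed table's). The CI method is recorded in the result
(`method_ci`); published CIs computed by unknown methods are not asserted
against it.

## Metacells

Within each (donor, subtype) stratum, cells with library size below 200
(a low cut-off chosen to preserve small microglial nuclei) are dropped and
the remainder partitioned into ⌈n/50⌉ seeded k-means groups on
log-normalized expression; degenerate geometries (duplicate profiles) fall
back to a balanced split. A metacell's expression is the arithmetic mean of
its members, which alleviates per-cell dropout. Strata below half the
target size become a single metacell with a warning. This is a simple,
documented stand-in for graph-based metacell construction: downstream
network statistics need only homogeneous, disjoint pools of averaged
profiles, and purity in (donor, subtype) is guaranteed by construction
here rather than by post-hoc splitting.

## Cell-specific networks

Genes enter network analysis if their expression rate exceeds 5% of cells
(strict inequality). For a query metacell and gene pair (x, y), windows on
each axis are `value ± h·s` with `h = 0.5` and `s` the SD of the nearest
10% of pool values on that axis — local-SD windows treat interior and
outlying query values with equal power, where quantile windows would not.
With n pool observations and window counts `n_x, n_y, n_xy`:

```
ρ = (n_xy − 1/2)/n − (n_x/n)(n_y/n)
z = ρ / sqrt(n_x n_y (n−n_x)(n−n_y) / (n⁴(n−1)))
```

and an edge is drawn when `z` exceeds the one-sided normal quantile at
`alpha_edge = 0.05`. Two numerical details matter for calibration and were
validated on simulated nulls: the query is excluded from its own window
counts (it always falls at the window centre on both axes, which otherwise
biases ρ upward — dramatically so for narrow windows), and the 0.5
continuity correction accounts for `n_xy` being a discrete count (without
it the empirical null edge rate was ≈ 0.061 at the 0.05 level for
500-observation pools; with it ≈ 0.03, i.e. slightly conservative).
Degenerate windows (s = 0) widen to the gene's smallest positive value
spacing; a fully constant gene yields `n_x = n` and z = 0. Genes with zero
expression in the query receive no edges, since dependence involving
non-expressed genes cannot be distinguished from dropout. Adjacency
matrices are symmetric with zero diagonal; populations of networks are
vectorized as upper-triangle 0/1 vectors, optionally restricted to an
ANOVA-selected gene panel (477 genes by default at full scale).

The pipeline pools all metacells for window statistics; constructing pools
per donor is supported by calling `csn_all` per stratum where enough
metacells exist (the statistic needs ≥ 20 pool observations).

## Energy-distance test

The two-sample statistic Q (above) uses the Euclidean norm raised to
`α = 1` by default; α is configurable in (0, 2), the range for which the
moment condition holds automatically for bounded 0/1 vectors. Within-group
terms with fewer than two members are defined as 0, so one-element groups
degrade gracefully. The permutation test redraws the group labels
(preserving k) `n_perm = 999` times and reports
`p = (1 + #{Q_perm ≥ Q_obs}) / (1 + n_perm)`, which is exactly valid under
exchangeability. Implementation detail: the pooled pairwise distance matrix
is computed once and every permutation's Q is obtained by masked
summations, so calibration experiments with hundreds of replicates run in
seconds. Pairwise subtype comparisons report unadjusted p-values in a
symmetric matrix with a unit diagonal.

## Pipeline

`run_pipeline` chains the stages with per-stage seeds derived by hashing
(global seed, stage name) — no hidden seed coupling — and writes TSV/JSON
artifacts plus a manifest of config hash and output checksums. Each stage
checkpoints its state; with `resume=True` a stage is reloaded only if its
checkpoint and all its outputs exist, and any invalidated stage forces
recomputation of everything downstream. Stage failures halt the run with
the stage name, leaving partial outputs in place.

## Problem sizes

The default synthetic cohort is 15 donors × 1,000 nuclei × 3,000 genes
(≈ 15k cells) — large enough that every planted effect is detectable with
comfortable margins while a full pipeline run stays around a minute.
Calibration suites use 500 replicates (permutation test), 1,000 null gene
pairs on 500-observation pools (CSN), and 200 replicates of 2 × 2,000
microglia (odds-ratio coverage).

## Known limitations

* The clustering backend is a stand-in for the original embedding-based
  algorithm; assignment probabilities are degenerate (1.0) and resolution
  values are not comparable across backends.
* Published real-data quantities (nuclei counts, DEG counts, KL medians,
  fold changes, metacell counts) depend on the unavailable raw data and are
  not reproduced; only formulas, limits, calibration and planted-effect
  recovery are asserted.
* The proportion analysis pools cells within conditions; donor-level
  compositional variance is not modelled.
* The CSN edge rule is one-sided (positive association only), matching
  co-expression heatmaps that depict non-negative connection strength.
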