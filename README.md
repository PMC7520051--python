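# armnet

Analysis toolkit for single-nucleus RNA-seq studies of microglial
heterogeneity in Alzheimer's disease — in particular the question of how
amyloid and tau pathology (the "AT score") and the *APOE* E4 / *TREM2* R47H
risk genotypes shift the balance between microglial subpopulations, most
notably the CD163-positive **amyloid-responsive microglia (ARM)**.

It is a library for Python users (see `examples/`), with a thin `armnet`
command-line wrapper for the common entry points.

## What it does

Given a sparse UMI count matrix with per-donor metadata (AT score, *APOE*,
*TREM2*), the package runs the full chain:

1. **QC** — keep nuclei with 200–4,000 expressed genes and <5%
   mitochondrial UMI; drop genes seen in <10 surviving cells.
2. **Preprocessing** — counts-per-10,000 normalization, log1p, selection of
   highly variable genes by mean-binned normalized dispersion, per-sample
   scaling to zero mean / unit variance.
3. **Multi-resolution clustering + consensus annotation** — Leiden or
   Louvain communities on a PCA–kNN graph at 15 resolutions (0.1–0.8);
   clusters are named by marker-set scores and a nucleus keeps a type label
   only when all resolutions agree (one disagreement tolerated for
   endothelial cells and OPCs).
4. **Batch-mixing diagnostic** — the regional KL divergence
   `KL = Σ_b p_b log(p_b/q_b)` between each sampled cell's k-nearest-
   neighbour batch composition `p` and the global composition `q`.
5. **Microglia subclustering** — re-cluster microglia, name subtypes by
   their marker programs (CX3CR1 homeostatic, FGD4 motile, CD163 ARM,
   FTL/FTH1 dystrophic), and flag doublet/contaminant subclusters that
   express foreign lineage markers and carry extra RNA.
6. **Differential expression** — Wilcoxon rank-sum per gene (tie- and
   continuity-corrected normal approximation), BH correction, significance
   at adjusted p < 0.05 and |log2FC| > 0.1, in `one_vs_homeostatic` and
   `one_vs_rest` modes; ANOVA gene ranking; AD-risk-gene z-score matrices.
7. **Proportion statistics** — subtype × condition 2×2 tables, odds ratios
   `ad/bc` with Woolf confidence intervals, two-sided Fisher exact tests.
8. **Metacells + cell-specific networks (CSN)** — partition cells into
   ~50-cell metacells pure in (donor, subtype); build one binary gene–gene
   network per metacell, where an edge means the statistic
   `ρ = n_xy/n − (n_x/n)(n_y/n)`, standardized by its variance under
   independence, exceeds the one-sided normal quantile. Windows are
   `value ± h·s` with `s` the standard deviation of the nearest fraction of
   pool values (local-SD windows); non-expressed genes get no edges.
9. **Energy-distance comparison** — subtype network populations are
   compared with the two-sample statistic

   ```
   Q(X,Y;α) = (2/n) Σ_i Σ_j |X_i − Y_j|^α
            − k(n−k)/n · C(k,2)⁻¹ Σ_{i<i'} |X_i − X_i'|^α
            − k(n−k)/n · C(n−k,2)⁻¹ Σ_{j<j'} |Y_j − Y_j'|^α
   ```

   with a label-permutation p-value.

A first-class **synthetic-data generator** (`armnet.simulate`) emulates the
statistical structure the analysis assumes — seven cortical cell types with
marker programs, gamma-Poisson counts with lognormal size factors,
per-(gene, sample) batch effects, mitochondrial fractions, doublets, and a
logistic model putting the planted AT/APOE/TREM2 effects on the ARM
membership odds — so every stage runs and is verified without any download.

## Worked example

```python
import numpy as np
from armnet import (default_design, simulate_dataset, filter_cells_genes,
                    cross_tab, cross_tab_or)

cm, truth, meta = simulate_dataset(default_design(seed=3))
mic = (truth.cell_type == "microglia") & ~truth.is_doublet
at = meta.lookup("at_score"); trem2 = meta.lookup("trem2")
cond = np.array([at[s] if trem2[s] == "WT" else "excluded"
                 for s in cm.sample_of_cell[mic]], dtype=object)
tab = cross_tab(truth.microglia_subtype[mic], cond, "arm", "A+T-", "A-T-")
res = cross_tab_or(tab)
print(f"OR {res.or_point:.3f}  CI [{res.ci_low:.3f}, {res.ci_high:.3f}]  "
      f"p {res.p_fisher:.2e}")
```

prints

```
OR 12.401  CI [5.359, 28.693]  p 1.72e-11
```

— ARM nuclei are ~12× more likely (on the odds scale) in amyloid-positive,
tau-negative donors than in pathology-free donors of this simulated cohort,
recovering the planted amyloid response. `examples/01`–`06` walk through
each capability the same way (QC, consensus annotation, batch mixing, DE,
proportions, networks) and print what the numbers mean.

The CLI wraps the same functions:

```bash
armnet simulate --out cohort/ --seed 0
armnet run-all --out run1 --seed 0
armnet compare --x arm_vectors.tsv --y motile_vectors.tsv --n-perm 999 --seed 0
```

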