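"""Differential expression and gene selection.

Wilcoxon rank-sum tests (normal approximation, tie and continuity
corrected) with Benjamini-Hochberg control within each comparison, in two
modes: every subpopulation against homeostatic microglia, or each against
the rest. Significance requires adjusted p < 0.05 and |log2 fold change| >
0.1, where fold change compares mean de-logged normalized expression with a
small pseudocount. Also: one-way-ANOVA gene ranking for network analysis
and group-mean z-score matrices for AD risk genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from armnet.qc import NormalizedMatrix

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9
DEFAULT_RISK_GENES = (
    "BIN1", "CELF1", "MS4A6A", "APOE", "TREM2", "SPP1", "PICALM", "SORL1",
    "ABCA7", "CD33", "CLU", "CR1", "INPP5D", "PLCG2", "HLA-DRB1", "PTK2B",
)


def rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum over gene columns.

    ``x``: n1 x G, ``y``: n2 x G. Returns (z, p) arrays of length G using
    the normal approximation with tie correction and a 0.5 continuity
    correction (the same convention as ``scipy.stats.mannwhitneyu`` with
    ``method="asymptotic"``). Columns where every value ties give p = 1.
    """
    n1, n2 = x.shape[0], y.shape[0]
    n = n1 + n2
    pooled = np.concatenate([x, y], axis=0)
    ranks = sps.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u = np.maximum(u1, n1 * n2 - u1)
    mu = n1 * n2 / 2.0
    # tie correction: sum over tie groups of t^3 - t, per column
    sorted_r = np.sort(ranks, axis=0)
    new_grp = np.ones_like(sorted_r, dtype=bool)
    new_grp[1:] = sorted_r[1:] != sorted_r[:-1]
    tie_term = np.empty(pooled.shape[1])
    for g in range(pooled.shape[1]):  # per-column tie runs
        _, counts = np.unique(sorted_r[:, g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (u - mu - 0.5) / np.maximum(sd, 1e-300), 0.0)
    z = np.maximum(z, 0.0)
    p = np.minimum(1.0, 2.0 * sps.norm.sf(z))
    # restore the sign of the group-1 shift for callers that want direction
    signed = np.where(u1 >= mu, z, -z)
    return signed, p


def log2_fold_change(x: np.ndarray, y: np.ndarray, log_input: bool = True) -> np.ndarray:
    """log2((mean expm1 x + eps) / (mean expm1 y + eps)) per gene column."""
    a = np.expm1(x) if log_input else x
    b = np.expm1(y) if log_input else y
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.log2((a.mean(axis=0) + LOG2FC_EPS) / (b.mean(axis=0) + LOG2FC_EPS))
    return np.nan_to_num(fc, nan=0.0, posinf=0.0, neginf=0.0)


def de_wilcoxon(
    nm: NormalizedMatrix,
    groups: np.ndarray,
    mode: str = "one_vs_rest",
    homeostatic_label: str = "homeostatic",
    min_cells: int = 3,
    alpha: float = 0.05,
    log2fc_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene Wilcoxon DE for each group, in one of the two modes.

    ``mode="one_vs_homeostatic"`` compares every non-homeostatic group to
    the homeostatic cells; ``mode="one_vs_rest"`` compares each group to
    all remaining cells. BH correction is applied across genes within each
    comparison. Input must be log-normalized, unscaled expression.
    Comparisons with fewer than ``min_cells`` cells on either side are
    skipped with a warning.
    """
    if mode not in ("one_vs_rest", "one_vs_homeostatic"):
        raise ValueError(f"unknown mode {mode!r}")
    groups = np.asarray(groups).astype(str)
    if groups.shape[0] != nm.n_cells:
        raise ValueError("one group label per cell required")
    names = sorted(np.unique(groups))
    rows = []
    for g in names:
        if mode == "one_vs_homeostatic":
            if g == homeostatic_label:
                continue
            ref_mask = groups == homeostatic_label
        else:
            ref_mask = groups != g
        g_mask = groups == g
        if g_mask.sum() < min_cells or ref_mask.sum() < min_cells:
            logger.warning(
                "skipping %s (%s): %d vs %d cells (< %d)",
                g, mode, int(g_mask.sum()), int(ref_mask.sum()), min_cells,
            )
            continue
        x, y = nm.values[g_mask], nm.values[ref_mask]
        _, p = rank_sum_z(x, y)
        lfc = log2_fold_change(x, y, log_input=nm.log_transformed)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        rows.append(
            pd.DataFrame(
                {
                    "gene": nm.gene_ids,
                    "group": g,
                    "mode": mode,
                    "log2fc": lfc,
                    "p": p,
                    "p_adj": np.maximum(p_adj, p),
                    "direction": np.where(lfc > 0, "up", "down"),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "group", "mode", "log2fc", "p", "p_adj",
                     "direction", "significant"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["significant"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > log2fc_threshold)
    return out


def select_genes_anova(
    expr: np.ndarray,
    labels: np.ndarray,
    n_select: int,
    gene_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Top ``n_select`` genes by one-way ANOVA p-value across groups.

    ``expr`` is observations x genes (cells or metacells); constant genes
    get p = 1 by convention. Returns gene indices (or IDs when
    ``gene_ids`` is given), ranked by ascending p with F as tie-break.
    """
    labels = np.asarray(labels).astype(str)
    expr = np.asarray(expr, dtype=float)
    names = np.unique(labels)
    if len(names) < 2:
        raise ValueError("ANOVA selection needs at least 2 groups")
    parts = [expr[labels == g] for g in names]
    if any(p.shape[0] < 2 for p in parts):
        raise ValueError("every group needs at least 2 observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = sps.f_oneway(*parts, axis=0)
    f = np.nan_to_num(np.asarray(f, dtype=float), nan=0.0)
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0  # constant genes
    n_genes = expr.shape[1]
    if n_select > n_genes:
        logger.warning("n_select=%d exceeds %d genes; returning all", n_select, n_genes)
    k = min(n_select, n_genes)
    order = np.lexsort((np.arange(n_genes), -f, p))
    top = order[:k]
    return gene_ids[top] if gene_ids is not None else top


def risk_gene_zscores(
    nm: NormalizedMatrix,
    group_of_cell: np.ndarray,
    risk_genes: tuple[str, ...] = DEFAULT_RISK_GENES,
    min_nonzero_frac: float = 0.2,
) -> pd.DataFrame:
    """Gene x group z-score matrix of group-mean expression for risk genes.

    Genes are kept only if they have non-zero expression in at least
    ``min_nonzero_frac`` of cells of at least one group; the retained
    genes' per-group means are z-scored across groups (population SD;
    constant genes give all-zero rows).
    """
    group_of_cell = np.asarray(group_of_cell).astype(str)
    names = sorted(np.unique(group_of_cell))
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    present = [g for g in risk_genes if g in gene_index]
    kept, means = [], []
    for g in present:
        col = nm.values[:, gene_index[g]]
        fracs = [np.mean(col[group_of_cell == name] > 0) for name in names]
        if max(fracs) >= min_nonzero_frac:
            kept.append(g)
            means.append([col[group_of_cell == name].mean() for name in names])
    if not kept:
        logger.warning("no risk gene passed the %.0f%% filter", 100 * min_nonzero_frac)
        return pd.DataFrame(columns=names)
    m = np.asarray(means)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=kept, columns=names)
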