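"""Cell-specific co-expression networks with local-SD windows.

For a query observation q (here a metacell) and a gene pair (x, y), the CSN
statistic asks whether observations near q's value of x are also near q's
value of y more often than independence predicts. Windows on each axis are
``value +/- h*s`` where s is the standard deviation of the
``neighborhood_frac`` fraction of pool values closest to the query on that
axis — a local-SD window that treats interior and outlying query values
with equal power. With n pool observations, n_x / n_y / n_xy inside the x
window, y window, and both:

    rho  = n_xy/n - (n_x/n)(n_y/n)
    z    = rho / sqrt(n_x * n_y * (n-n_x) * (n-n_y) / (n^4 * (n-1)))

and an edge is drawn when z exceeds the one-sided normal quantile at
``alpha_edge``. Genes not expressed in the query receive no edges (their
dependence cannot be told apart from dropout), and degenerate windows
(s = 0) are widened to the smallest positive spacing of that gene's values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

MIN_POOL = 20


@dataclass
class Csn:
    """One metacell's binary gene-gene network (symmetric, zero diagonal)."""

    adjacency: np.ndarray  # genes x genes, uint8
    query_index: int
    z_threshold: float
    window_scale: float
    neighborhood_frac: float
    gene_ids: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _local_sd_windows(
    expr: np.ndarray, query: np.ndarray, h: float, frac: float
) -> np.ndarray:
    """Boolean in-window matrix W[p, g] for every pool point and gene."""
    n, n_genes = expr.shape
    m = max(2, math.ceil(frac * n))
    dist = np.abs(expr - query[None, :])
    nearest = np.argpartition(dist, m - 1, axis=0)[:m]
    local = np.take_along_axis(expr, nearest, axis=0)
    s = local.std(axis=0, ddof=0)
    # degenerate window: widen to the smallest positive spacing of the gene
    for g in np.where(s <= 0)[0]:
        vals = np.unique(expr[:, g])
        gaps = np.diff(vals)
        s[g] = gaps.min() if gaps.size else 0.0
    half = h * s
    return dist <= half[None, :]


def csn_one(
    expr: np.ndarray,
    query_index: int,
    alpha_edge: float = 0.05,
    h: float = 0.5,
    neighborhood_frac: float = 0.1,
    gene_ids: np.ndarray | None = None,
) -> Csn:
    """Network for one query observation against the whole pool.

    ``expr`` is the pool (observations x genes, the query row included).
    Pairs where either gene is zero at the query get no edge; pairs with
    empty or full windows (n_x in {0, n}) give z = 0 (no evidence).
    """
    expr = np.asarray(expr, dtype=float)
    n, n_genes = expr.shape
    if n < MIN_POOL:
        raise ValueError(f"need >= {MIN_POOL} observations in the pool, got {n}")
    if not 0 <= query_index < n:
        raise IndexError("query_index out of range")
    if not 0.0 < alpha_edge < 1.0:
        raise ValueError("alpha_edge must be in (0, 1)")
    if h <= 0 or not 0.0 < neighborhood_frac <= 1.0:
        raise ValueError("h must be > 0 and neighborhood_frac in (0, 1]")

    query = expr[query_index]
    w = _local_sd_windows(expr, query, h, neighborhood_frac)
    # the query always lies in its own window on both axes; counting it
    # would bias rho upward for narrow windows, so counts run over the
    # other pool observations only
    w[query_index, :] = False
    wf = w.astype(float)
    n = n - 1
    n_x = wf.sum(axis=0)
    n_xy = wf.T @ wf
    # 0.5 continuity correction: n_xy is a discrete count, and without it
    # the normal approximation rejects slightly above the nominal level
    rho = (n_xy - 0.5) / n - np.outer(n_x, n_x) / (n * n)
    var = (
        np.outer(n_x, n_x)
        * np.outer(n - n_x, n - n_x)
        / (float(n) ** 4 * (n - 1))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, rho / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    thresh = float(sps.norm.ppf(1.0 - alpha_edge))
    adj = (z > thresh).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    silent = query <= 0
    adj[silent, :] = 0
    adj[:, silent] = 0
    return Csn(
        adjacency=adj,
        query_index=query_index,
        z_threshold=thresh,
        window_scale=h,
        neighborhood_frac=neighborhood_frac,
        gene_ids=gene_ids,
    )


def csn_all(
    expr: np.ndarray,
    alpha_edge: float = 0.05,
    h: float = 0.5,
    neighborhood_frac: float = 0.1,
    gene_ids: np.ndarray | None = None,
) -> list[Csn]:
    """One network per pool observation."""
    expr = np.asarray(expr, dtype=float)
    return [
        csn_one(expr, q, alpha_edge=alpha_edge, h=h,
                neighborhood_frac=neighborhood_frac, gene_ids=gene_ids)
        for q in range(expr.shape[0])
    ]


def average_adjacency(csns: list[Csn]) -> np.ndarray:
    """Mean adjacency over a set of networks (connection-strength matrix)."""
    if not csns:
        raise ValueError("no networks to average")
    return np.mean([c.adjacency for c in csns], axis=0)


def vectorize_csns(csns: list[Csn], gene_subset: np.ndarray | None = None) -> np.ndarray:
    """Stack upper-triangle adjacency entries into k x (G choose 2) vectors.

    ``gene_subset`` (indices) restricts the adjacency to a gene panel — for
    instance the ANOVA-selected genes — before vectorizing.
    """
    if not csns:
        raise ValueError("no networks to vectorize")
    rows = []
    for c in csns:
        adj = c.adjacency
        if gene_subset is not None:
            adj = adj[np.ix_(gene_subset, gene_subset)]
        iu = np.triu_indices(adj.shape[0], k=1)
        rows.append(adj[iu].astype(float))
    return np.vstack(rows)
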