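"""KL-divergence diagnostic of batch mixing with regional kNN sampling.

For N randomly sampled query cells, the divergence KL = sum_b p_b log(p_b/q_b)
compares the batch composition p of each query's K-nearest-neighbour
region against the global composition q (natural log; 0*log 0 := 0). A
median near zero means batches are locally interchangeable — the signature
of successful batch-effect removal; large values flag regions dominated by
single batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class BatchMixingConfig:
    N: int = 100  # sampled query cells
    K: int = 100  # nearest neighbours per query
    space: str = "embedding"  # label for reporting: embedding | scaled_expression
    seed: int = 0
    include_self: bool = False  # whether the query joins its own region

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class BatchMixingResult:
    kl_values: np.ndarray
    median_kl: float
    global_props: dict[str, float]
    config: BatchMixingConfig

    def to_dict(self) -> dict:
        return {
            "median_kl": self.median_kl,
            "kl_values": [float(v) for v in self.kl_values],
            "global_props": self.global_props,
            "N": self.config.N,
            "K": self.config.K,
            "space": self.config.space,
            "seed": self.config.seed,
        }


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """sum p log(p/q) with the 0*log 0 := 0 convention (natural log)."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_batch_mixing(
    coords: np.ndarray,
    batch_of_cell: np.ndarray,
    cfg: BatchMixingConfig | None = None,
) -> BatchMixingResult:
    """Regional batch-mixing KL divergence over seeded random query cells.

    Queries are sampled without replacement (all cells if N exceeds the
    population). Each query's region is its K Euclidean nearest neighbours,
    excluding the query itself unless ``include_self``.
    """
    cfg = cfg or BatchMixingConfig()
    coords = np.asarray(coords, dtype=float)
    batch_of_cell = np.asarray(batch_of_cell)
    n = coords.shape[0]
    if batch_of_cell.shape[0] != n:
        raise ValueError("one batch label per cell required")
    if cfg.K >= n:
        raise ValueError(f"K={cfg.K} must be smaller than the number of cells ({n})")

    batches, inv = np.unique(batch_of_cell.astype(str), return_inverse=True)
    q = np.bincount(inv, minlength=len(batches)).astype(float)
    q /= q.sum()

    rng = np.random.default_rng(cfg.seed)
    n_query = min(cfg.N, n)
    queries = rng.choice(n, size=n_query, replace=False)

    nn = NearestNeighbors(n_neighbors=cfg.K + (0 if cfg.include_self else 1)).fit(coords)
    _, idx = nn.kneighbors(coords[queries])
    kl = np.empty(n_query)
    for r, qi in enumerate(queries):
        neigh = idx[r]
        if not cfg.include_self:
            neigh = neigh[neigh != qi][: cfg.K]
        p = np.bincount(inv[neigh], minlength=len(batches)).astype(float)
        p /= p.sum()
        kl[r] = kl_divergence(p, q)
    return BatchMixingResult(
        kl_values=kl,
        median_kl=float(np.median(kl)),
        global_props={b: float(v) for b, v in zip(batches, q)},
        config=cfg,
    )
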