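"""Energy-distance two-sample statistic on vectorized networks.

For samples X_1..X_k ~ F1 and Y_{k+1}..Y_n ~ F2 of equal-length vectors the
statistic is

    Q = (2/n) sum_i sum_j |X_i - Y_j|^a
        - k(n-k)/n * C(k,2)^{-1}    sum_{i<i'} |X_i - X_i'|^a
        - k(n-k)/n * C(n-k,2)^{-1}  sum_{j<j'} |Y_j - Y_j'|^a

with |.| the Euclidean norm and a in (0, 2) (finite a-th moments are
automatic for 0/1 network vectors). Q is zero in expectation under
H0: F1 = F2 and grows with between-group separation; significance comes
from a label-permutation test with the +1-corrected p-value. A within-group
term with fewer than two members is defined as 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class EnergyTestResult:
    q: float
    p_perm: float
    n_perm: int
    seed: int
    k: int
    n: int
    alpha: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in the open interval (0, 2), got {alpha}")


def _q_from_distance(d: np.ndarray, in_x: np.ndarray) -> float:
    """Q given the pooled pairwise |.|^alpha matrix and a group mask."""
    n = d.shape[0]
    k = int(in_x.sum())
    nk = n - k
    cross = float(in_x @ d @ (~in_x))
    q = 2.0 / n * cross
    scale = k * nk / n
    if k >= 2:
        within_x = float(in_x @ d @ in_x) / 2.0
        q -= scale * within_x / (k * (k - 1) / 2.0)
    if nk >= 2:
        within_y = float((~in_x) @ d @ (~in_x)) / 2.0
        q -= scale * within_y / (nk * (nk - 1) / 2.0)
    return q


def energy_q(X: np.ndarray, Y: np.ndarray, alpha: float = 1.0) -> float:
    """The energy statistic Q for two samples of vectors (rows)."""
    _check_alpha(alpha)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same vector length")
    pooled = np.vstack([X, Y])
    d = cdist(pooled, pooled) ** alpha
    in_x = np.zeros(pooled.shape[0], dtype=bool)
    in_x[: X.shape[0]] = True
    return _q_from_distance(d, in_x)


def energy_test(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float = 1.0,
    n_perm: int = 999,
    seed: int = 0,
) -> EnergyTestResult:
    """Permutation test of H0: F1 = F2 with the observed group sizes.

    ``n_perm`` seeded label permutations preserve k; the p-value is
    (1 + #{Q_perm >= Q_obs}) / (1 + n_perm). Deterministic given ``seed``.
    """
    _check_alpha(alpha)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same vector length")
    k, n = X.shape[0], X.shape[0] + Y.shape[0]
    pooled = np.vstack([X, Y])
    d = cdist(pooled, pooled) ** alpha
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:k] = True
    q_obs = _q_from_distance(d, obs_mask)

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=float)
    for r in range(n_perm):
        masks[r, rng.permutation(n)[:k]] = 1.0
    q_perm = _q_batch(d, masks, k)
    p = (1.0 + float(np.sum(q_perm >= q_obs))) / (1.0 + n_perm)
    return EnergyTestResult(
        q=q_obs, p_perm=p, n_perm=n_perm, seed=seed, k=k, n=n, alpha=alpha
    )


def _q_batch(d: np.ndarray, masks: np.ndarray, k: int) -> np.ndarray:
    """Vectorized Q over many group masks (rows of ``masks``, entries 0/1)."""
    n = d.shape[0]
    nk = n - k
    md = masks @ d  # n_perm x n
    within_x = np.einsum("pi,pi->p", md, masks) / 2.0
    cross = np.einsum("pi,pi->p", md, 1.0 - masks)
    total = d.sum() / 2.0
    within_y = total - within_x - cross
    q = 2.0 / n * cross
    scale = k * nk / n
    if k >= 2:
        q = q - scale * within_x / (k * (k - 1) / 2.0)
    if nk >= 2:
        q = q - scale * within_y / (nk * (nk - 1) / 2.0)
    return q


def pairwise_subtype_tests(
    vectors_by_subtype: dict[str, np.ndarray],
    alpha: float = 1.0,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Energy test for every unordered subtype pair; unadjusted p-values.

    ``vectors_by_subtype`` maps subtype name -> k x L array of vectorized
    networks (at least 2 per subtype). Returns a symmetric p-value matrix
    with 1.0 on the diagonal.
    """
    names = sorted(vectors_by_subtype)
    for name in names:
        if np.atleast_2d(vectors_by_subtype[name]).shape[0] < 2:
            raise ValueError(f"subtype {name!r} needs at least 2 network vectors")
    if len(names) < 2:
        raise ValueError("need at least 2 subtypes")
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        res = energy_test(
            vectors_by_subtype[names[i]],
            vectors_by_subtype[names[j]],
            alpha=alpha,
            n_perm=n_perm,
            seed=seed + 1009 * i + j,
        )
        p.iloc[i, j] = p.iloc[j, i] = res.p_perm
    return p
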