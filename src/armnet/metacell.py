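"""Metacell aggregation: disjoint clusters of homogeneous profiles.

Single nuclei are too sparse for per-cell network inference, so cells are
partitioned — within each (subject, subtype) stratum, after dropping
low-library cells — into groups of roughly ``target_size`` cells by seeded
k-means on log-normalized expression. A metacell's expression is the
arithmetic mean of its members, and metacells are pure in subject and
subtype by construction. This is a deliberately simple stand-in for
graph-based metacell algorithms: the downstream network statistics only
need homogeneous, disjoint pools of averaged profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from armnet.qc import NormalizedMatrix
from armnet.simulate import CountMatrix

logger = logging.getLogger(__name__)


def gene_filter_expression_rate(
    m: CountMatrix, min_rate: float = 0.05
) -> np.ndarray:
    """Boolean flags for genes with nonzero counts in > ``min_rate`` of cells.

    The comparison is strict, so ``min_rate=0`` keeps every gene expressed
    in at least one cell.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    frac = np.asarray((m.counts > 0).sum(axis=0)).ravel() / m.n_cells
    return frac > min_rate


@dataclass
class MetacellSet:
    """A partition of retained cells into (subject, subtype)-pure metacells."""

    assignment: np.ndarray  # per retained cell: metacell index
    cell_index: np.ndarray  # indices of retained cells in the source matrix
    expr: np.ndarray  # metacells x genes mean expression
    sizes: np.ndarray  # member counts per metacell
    subject_of_metacell: np.ndarray
    subtype_of_metacell: np.ndarray
    min_library: int
    target_size: int

    @property
    def n_metacells(self) -> int:
        return self.expr.shape[0]


def build_metacells(
    nm: NormalizedMatrix,
    subject_of_cell: np.ndarray,
    subtype_of_cell: np.ndarray,
    target_size: int = 50,
    min_library: int = 200,
    seed: int = 0,
) -> MetacellSet:
    """Partition cells into metacells of ~``target_size`` within strata.

    Within each (subject, subtype) stratum, cells with raw library size
    below ``min_library`` are dropped (the low cut-off preserves small
    cells such as microglia), and the remainder are split into
    ceil(n / target_size) seeded k-means groups on the log-normalized
    values. Strata with fewer than ``target_size / 2`` cells become a
    single metacell with a warning.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    subject_of_cell = np.asarray(subject_of_cell).astype(str)
    subtype_of_cell = np.asarray(subtype_of_cell).astype(str)
    if subject_of_cell.shape[0] != nm.n_cells or subtype_of_cell.shape[0] != nm.n_cells:
        raise ValueError("per-cell subject and subtype labels required")
    lib = nm.library_size
    if lib is None:
        raise ValueError("NormalizedMatrix.library_size required for the library filter")

    assignment_parts: list[np.ndarray] = []
    index_parts: list[np.ndarray] = []
    expr_rows: list[np.ndarray] = []
    sizes: list[int] = []
    mc_subject: list[str] = []
    mc_subtype: list[str] = []
    next_id = 0
    strata = sorted(
        set(zip(subject_of_cell.tolist(), subtype_of_cell.tolist()))
    )
    for si, (subj, subt) in enumerate(strata):
        mask = (subject_of_cell == subj) & (subtype_of_cell == subt) & (
            lib >= min_library
        )
        idx = np.where(mask)[0]
        n = idx.size
        if n == 0:
            continue
        if n < target_size / 2:
            logger.warning(
                "stratum (%s, %s) has %d cells (< %d/2): single metacell",
                subj, subt, n, target_size,
            )
            labels = np.zeros(n, dtype=int)
            k = 1
        else:
            k = math.ceil(n / target_size)
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=k, random_state=seed + si, n_init=4)
                labels = km.fit_predict(nm.values[idx])
                if len(np.unique(labels)) < k:
                    # degenerate geometry (e.g. duplicate profiles): fall
                    # back to a balanced split so metacells keep ~target size
                    labels = (np.arange(n) * k) // n
        for c in np.unique(labels):
            members = idx[labels == c]
            expr_rows.append(nm.values[members].mean(axis=0))
            sizes.append(members.size)
            mc_subject.append(subj)
            mc_subtype.append(subt)
            assignment_parts.append(np.full(members.size, next_id))
            index_parts.append(members)
            next_id += 1
    if next_id == 0:
        raise ValueError("no cells survived the library filter")
    order = np.argsort(np.concatenate(index_parts), kind="stable")
    return MetacellSet(
        assignment=np.concatenate(assignment_parts)[order],
        cell_index=np.concatenate(index_parts)[order],
        expr=np.vstack(expr_rows),
        sizes=np.asarray(sizes),
        subject_of_metacell=np.asarray(mc_subject, dtype=object),
        subtype_of_metacell=np.asarray(mc_subtype, dtype=object),
        min_library=min_library,
        target_size=target_size,
    )
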