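"""Multi-resolution graph clustering, marker annotation and consensus labels.

Cells are clustered at a ladder of resolutions (default 0.1-0.8, step 0.05)
by Leiden or Louvain community detection on a kNN graph built in PCA space.
Each cluster is annotated with the cell type whose marker set has the
highest mean standardized expression, and a nucleus receives a final label
only when enough of its per-resolution type labels agree (all resolutions
by default; one fewer for rare or hard-to-separate types such as
endothelial cells and OPCs). Microglia subclusters dominated by another
lineage's markers — doublets and contaminants — are flagged and removed.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from armnet.qc import NormalizedMatrix

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"

DEFAULT_RESOLUTIONS: tuple[float, ...] = tuple(
    round(0.1 + 0.05 * i, 2) for i in range(15)
)

#: Marker table for consensus annotation (type -> marker gene set).
DEFAULT_MARKERS: dict[str, frozenset[str]] = {
    "microglia": frozenset({"CX3CR1", "C1QB", "CSF1R", "P2RY12", "TMEM119"}),
    "excitatory_neuron": frozenset({"SLC17A7", "GRIN1", "GRIN2B", "SATB2", "RORB"}),
    "inhibitory_neuron": frozenset({"GAD1", "GAD2", "SLC32A1", "PVALB", "SST"}),
    "astrocyte": frozenset({"AQP4", "GFAP", "SLC1A2", "ALDH1L1", "GJA1"}),
    "oligodendrocyte": frozenset({"MBP", "MOG", "OLIG1", "PLP1", "MAG"}),
    "opc": frozenset({"PDGFRA", "CSPG4", "SOX10", "LHFPL3", "OLIG2"}),
    "endothelial": frozenset({"CLDN5", "FLT1", "PECAM1", "VWF", "A2M"}),
}

#: Marker programs used to name microglia subclusters.
MICROGLIA_SUBTYPE_MARKERS: dict[str, frozenset[str]] = {
    "homeostatic": frozenset({"CX3CR1", "SELPLG", "MEF2A"}),
    "motile": frozenset({"FGD4", "ARHGAP15", "ARHGAP24", "BMP2K", "FOXP1"}),
    "arm": frozenset({"CD163", "SPP1", "C1QA", "FCGBP", "SLC11A1"}),
    "dystrophic": frozenset({"FTL", "FTH1", "SKAP2"}),
}


@dataclass
class MultiResolutionLabels:
    """Per-cell cluster IDs across resolutions, plus the clustering embedding.

    ``max_prob`` is the backend's assignment confidence; hard-assignment
    backends (Leiden/Louvain) report 1.0.
    """

    resolutions: tuple[float, ...]
    labels: np.ndarray  # cells x resolutions, int
    max_prob: np.ndarray  # cells x resolutions, in [0, 1]
    embedding: np.ndarray  # cells x d

    def __post_init__(self) -> None:
        if self.labels.shape != self.max_prob.shape:
            raise ValueError("labels and max_prob must have the same shape")
        if self.labels.shape[1] != len(self.resolutions):
            raise ValueError("one label column per resolution required")
        if np.any(self.max_prob < 0) or np.any(self.max_prob > 1):
            raise ValueError("max_prob must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]


@dataclass
class ConsensusRule:
    """Agreement counts required per type (default: all R resolutions).

    ``relaxed_types`` require only R-1 agreeing labels — used for
    endothelial cells and OPCs, which merge with neighbours at the lowest
    resolution.
    """

    n_resolutions: int
    relaxed_types: frozenset[str] = frozenset({"endothelial", "opc"})
    relaxation: int = 1

    def required(self, cell_type: str) -> int:
        r = self.n_resolutions
        if cell_type in self.relaxed_types:
            r -= self.relaxation
        return max(1, min(r, self.n_resolutions))


def knn_graph(embedding: np.ndarray, n_neighbors: int = 15) -> ig.Graph:
    """Undirected kNN graph (union of directed neighbour lists)."""
    n = embedding.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    src = np.repeat(np.arange(n), n_neighbors)
    dst = idx[:, 1:].ravel()  # drop self
    edges = {(min(a, b), max(a, b)) for a, b in zip(src.tolist(), dst.tolist())}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_multiresolution(
    nm: NormalizedMatrix,
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS,
    backend: str = "leiden",
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
) -> MultiResolutionLabels:
    """Cluster the scaled HVG matrix at every resolution.

    PCA embedding of the (scaled) HVG columns -> kNN graph -> community
    detection per resolution. Deterministic given ``seed``.
    """
    if not resolutions:
        raise ValueError("at least one resolution is required")
    if backend not in ("leiden", "louvain"):
        raise ValueError(f"unknown backend {backend!r}")
    x = nm.hvg_values() if nm.hvg_flags is not None else nm.values
    n_comp = min(n_pcs, x.shape[1], max(1, x.shape[0] - 1))
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    g = knn_graph(emb, n_neighbors=n_neighbors)

    labels = np.empty((nm.n_cells, len(resolutions)), dtype=int)
    for j, res in enumerate(resolutions):
        if backend == "leiden":
            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=float(res),
                seed=seed,
                n_iterations=2,
            )
            membership = part.membership
        else:
            _random.seed(seed * 100003 + j)  # igraph draws from Python's RNG
            membership = g.community_multilevel(resolution=float(res)).membership
        labels[:, j] = membership
    logger.info(
        "clustered %d cells at %d resolutions (%s backend): %s clusters",
        nm.n_cells, len(resolutions), backend,
        [int(labels[:, j].max()) + 1 for j in range(len(resolutions))],
    )
    return MultiResolutionLabels(
        resolutions=tuple(float(r) for r in resolutions),
        labels=labels,
        max_prob=np.ones_like(labels, dtype=float),
        embedding=emb,
    )


def marker_scores(
    nm: NormalizedMatrix, markers: dict[str, frozenset[str]]
) -> tuple[np.ndarray, list[str]]:
    """Per-cell mean standardized expression of each type's marker set.

    Genes are z-scored across all cells; marker genes absent from the
    matrix are ignored (a type with no present markers scores NaN and is
    never assigned).
    """
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    types = sorted(markers)
    scores = np.full((nm.n_cells, len(types)), np.nan)
    mu = nm.values.mean(axis=0)
    sd = nm.values.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    for t, name in enumerate(types):
        idx = [gene_index[g] for g in markers[name] if g in gene_index]
        if not idx:
            logger.warning("no marker genes of type %r present; never assigned", name)
            continue
        z = (nm.values[:, idx] - mu[idx]) / sd[idx]
        scores[:, t] = z.mean(axis=1)
    return scores, types


def annotate_clusters(
    mrl: MultiResolutionLabels,
    nm: NormalizedMatrix,
    markers: dict[str, frozenset[str]] = DEFAULT_MARKERS,
    tie_tol: float = 1e-9,
) -> list[dict[int, tuple[str | None, float]]]:
    """Assign each cluster, at each resolution, the best-scoring type.

    Returns one ``{cluster_id: (type or None, margin)}`` map per resolution;
    a tie between the top two types leaves the cluster unassigned (None),
    which counts as disagreement in the consensus step.
    """
    cell_scores, types = marker_scores(nm, markers)
    maps: list[dict[int, tuple[str | None, float]]] = []
    for j in range(len(mrl.resolutions)):
        cluster_map: dict[int, tuple[str | None, float]] = {}
        for c in np.unique(mrl.labels[:, j]):
            mask = mrl.labels[:, j] == c
            with np.errstate(invalid="ignore"):
                mean_scores = np.nanmean(cell_scores[mask], axis=0)
            valid = ~np.isnan(mean_scores)
            if not valid.any():
                cluster_map[int(c)] = (None, 0.0)
                continue
            order = np.argsort(
                np.where(valid, mean_scores, -np.inf), kind="stable"
            )[::-1]
            best, second = order[0], (order[1] if len(order) > 1 else None)
            margin = (
                float(mean_scores[best] - mean_scores[second])
                if second is not None and valid[second]
                else float("inf")
            )
            if margin <= tie_tol:
                cluster_map[int(c)] = (None, margin)
            else:
                cluster_map[int(c)] = (types[best], margin)
        maps.append(cluster_map)
    return maps


def consensus_annotate(
    mrl: MultiResolutionLabels,
    per_resolution_maps: list[dict[int, tuple[str | None, float]]],
    rule: ConsensusRule | None = None,
) -> np.ndarray:
    """Per-cell consensus type label, or ``"unannotated"``.

    A cell is labeled T iff at least ``rule.required(T)`` of its
    per-resolution type labels equal T. The result is invariant to the
    ordering of resolutions (only counts matter).
    """
    rule = rule or ConsensusRule(n_resolutions=len(mrl.resolutions))
    votes_per_cell = []
    for j, cmap in enumerate(per_resolution_maps):
        votes_per_cell.append(
            np.array(
                [cmap.get(int(c), (None, 0.0))[0] for c in mrl.labels[:, j]],
                dtype=object,
            )
        )
    votes = np.stack(votes_per_cell, axis=1)  # cells x resolutions
    out = np.array([UNANNOTATED] * mrl.n_cells, dtype=object)
    for i in range(mrl.n_cells):
        counts: dict[str, int] = {}
        for v in votes[i]:
            if v is not None:
                counts[v] = counts.get(v, 0) + 1
        best_type, best_count = None, 0
        for t, c in counts.items():
            if c >= rule.required(t) and c > best_count:
                best_type, best_count = t, c
        if best_type is not None:
            out[i] = best_type
    return out


def flag_contaminant_subclusters(
    sub_labels: np.ndarray,
    nm: NormalizedMatrix,
    markers: dict[str, frozenset[str]] = DEFAULT_MARKERS,
    mean_genes_per_cluster: dict[int, float] | None = None,
    microglia_type: str = "microglia",
    z_threshold: float = 2.0,
    score_threshold: float = 0.5,
) -> dict[int, bool]:
    """Flag microglia subclusters that look like doublets/contaminants.

    A subcluster is flagged when (a) its mean standardized expression of
    some non-microglial marker set both stands out from the other
    subclusters by more than ``z_threshold`` SDs and is positively elevated
    (above ``score_threshold`` on the per-gene z scale — a genuinely
    microglial cluster does not express foreign lineage markers at all)
    AND (b) its mean detected-genes per cell exceeds the median over the
    non-candidate subclusters (contaminating doublets carry more genes and
    RNA).

    Raises ``ValueError`` if every subcluster would be flagged (suggests
    mis-specified markers).
    """
    clusters = [int(c) for c in np.unique(sub_labels)]
    other_types = {t: s for t, s in markers.items() if t != microglia_type}
    if not other_types:
        logger.warning("empty (non-microglial) marker table: nothing flagged")
        return {c: False for c in clusters}
    cell_scores, types = marker_scores(nm, other_types)
    present = [t for t in range(len(types)) if not np.all(np.isnan(cell_scores[:, t]))]
    if not present:
        logger.warning("no non-microglial marker genes present: nothing flagged")
        return {c: False for c in clusters}

    score_by_cluster = np.stack(
        [np.nanmean(cell_scores[sub_labels == c], axis=0) for c in clusters]
    )  # clusters x types
    if mean_genes_per_cluster is None:
        detected = (nm.values > 0).sum(axis=1)
        mean_genes_per_cluster = {
            c: float(detected[sub_labels == c].mean()) for c in clusters
        }

    candidates: set[int] = set()
    if len(clusters) >= 2:
        for ci, c in enumerate(clusters):
            others = np.delete(score_by_cluster, ci, axis=0)
            mu = np.nanmean(others, axis=0)
            sd = np.nanstd(others, axis=0)
            sd = np.where(sd > 0, sd, 1e-12)
            z = (score_by_cluster[ci] - mu) / sd
            elevated = score_by_cluster[ci] > score_threshold
            if np.any((z > z_threshold) & elevated & np.isin(
                np.arange(len(types)), present
            )):
                candidates.add(c)
    unflagged = [c for c in clusters if c not in candidates]
    ref = (
        float(np.median([mean_genes_per_cluster[c] for c in unflagged]))
        if unflagged
        else -np.inf
    )
    flags = {
        c: (c in candidates) and (mean_genes_per_cluster[c] > ref) for c in clusters
    }
    if clusters and all(flags.values()):
        raise ValueError(
            "every subcluster flagged as contaminant; check the marker table"
        )
    return flags
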