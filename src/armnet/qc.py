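"""Quality control and the normalize -> log1p -> HVG -> per-sample scaling chain.

Cell filters keep nuclei whose expressed-gene count lies in a closed interval
(default [200, 4000]) and whose mitochondrial UMI fraction is strictly below a
cap (default 5%); genes expressed in fewer than a floor of surviving cells
(default 10) are then dropped. Normalization rescales each cell to a common
total (default 10,000 counts) followed by natural log1p. Highly variable genes
are ranked by mean-binned normalized dispersion, and scaling standardizes each
HVG to zero mean / unit variance within each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from armnet.simulate import CountMatrix

logger = logging.getLogger(__name__)


class AllCellsFilteredError(ValueError):
    """Raised when QC removes every cell (or every gene)."""


@dataclass
class QcThresholds:
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 4000
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be <= max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be >= 0")


@dataclass
class QcReport:
    """Removal counts per criterion (a cell may violate several)."""

    n_cells_in: int
    n_cells_below_gene_floor: int
    n_cells_above_gene_ceiling: int
    n_cells_above_mito_cap: int
    n_cells_removed: int
    n_cells_kept: int
    n_genes_in: int
    n_genes_below_cell_floor: int
    n_genes_kept: int

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_cells_genes(
    m: CountMatrix, t: QcThresholds | None = None
) -> tuple[CountMatrix, QcReport]:
    """Apply cell filters, then the gene filter, in a single pass.

    Cells are kept when their expressed-gene count (counts > 0) lies in the
    closed interval [min, max] AND their mitochondrial UMI fraction is
    strictly below the cap; genes expressed in fewer than
    ``min_cells_per_gene`` of the *surviving* cells are then dropped. The
    gene filter is not followed by a second cell pass (single-pass
    convention; re-filtering cells afterwards could remove more).
    """
    t = t or QcThresholds()
    genes_per_cell = m.genes_per_cell()
    mito_frac = m.mito_fraction()
    low = genes_per_cell < t.min_genes_per_cell
    high = genes_per_cell > t.max_genes_per_cell
    mito_bad = mito_frac >= t.max_mito_fraction
    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise AllCellsFilteredError("all cells removed by QC thresholds")

    sub = m.counts[keep_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= t.min_cells_per_gene
    if not keep_genes.any():
        raise AllCellsFilteredError("all genes removed by QC thresholds")

    out = CountMatrix(
        counts=sub[:, keep_genes].tocsr(),
        gene_ids=m.gene_ids[keep_genes],
        cell_ids=m.cell_ids[keep_cells],
        sample_of_cell=m.sample_of_cell[keep_cells],
        mito_gene_flags=m.mito_gene_flags[keep_genes],
    )
    report = QcReport(
        n_cells_in=m.n_cells,
        n_cells_below_gene_floor=int(low.sum()),
        n_cells_above_gene_ceiling=int(high.sum()),
        n_cells_above_mito_cap=int(mito_bad.sum()),
        n_cells_removed=int((~keep_cells).sum()),
        n_cells_kept=int(keep_cells.sum()),
        n_genes_in=m.n_genes,
        n_genes_below_cell_floor=int((~keep_genes).sum()),
        n_genes_kept=int(keep_genes.sum()),
    )
    logger.info(
        "QC kept %d/%d cells and %d/%d genes "
        "(floor<%d: %d, ceiling>%d: %d, mito>=%.3g: %d)",
        report.n_cells_kept, report.n_cells_in,
        report.n_genes_kept, report.n_genes_in,
        t.min_genes_per_cell, report.n_cells_below_gene_floor,
        t.max_genes_per_cell, report.n_cells_above_gene_ceiling,
        t.max_mito_fraction, report.n_cells_above_mito_cap,
    )
    return out, report


@dataclass
class NormalizedMatrix:
    """Dense cells x genes expression values after normalization.

    ``values`` are counts-per-``per_cell_target`` (optionally log1p'ed,
    optionally scaled on HVG columns). ``library_size`` keeps the raw
    per-cell UMI totals so later stages (metacell library filtering) do not
    need the count matrix.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_of_cell: np.ndarray
    per_cell_target: float = 10000.0
    log_transformed: bool = False
    hvg_flags: np.ndarray | None = None
    scaling_scope: str | None = None  # None | "per_sample" | "global"
    library_size: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def hvg_values(self) -> np.ndarray:
        if self.hvg_flags is None:
            raise ValueError("HVGs have not been selected")
        return self.values[:, self.hvg_flags]

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        return NormalizedMatrix(
            values=self.values[mask],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[mask],
            sample_of_cell=self.sample_of_cell[mask],
            per_cell_target=self.per_cell_target,
            log_transformed=self.log_transformed,
            hvg_flags=None if self.hvg_flags is None else self.hvg_flags.copy(),
            scaling_scope=self.scaling_scope,
            library_size=None if self.library_size is None else self.library_size[mask],
        )


def normalize_log(
    m: CountMatrix, target: float = 10000.0, log: bool = True
) -> NormalizedMatrix:
    """Scale each cell to ``target`` total counts, then natural log1p.

    All-zero cells are left as zero rows (with a logged warning).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    lib = m.library_sizes().astype(float)
    n_zero = int((lib == 0).sum())
    if n_zero:
        logger.warning("%d all-zero cells left as zero rows", n_zero)
    scale = np.where(lib > 0, target / np.maximum(lib, 1e-300), 0.0)
    values = m.counts.multiply(scale[:, None]).toarray()
    if log:
        np.log1p(values, out=values)
    return NormalizedMatrix(
        values=values,
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        sample_of_cell=m.sample_of_cell.copy(),
        per_cell_target=target,
        log_transformed=log,
        library_size=lib,
    )


def select_hvg(nm: NormalizedMatrix, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Flag the ``min(n_top, n_genes)`` most variable genes.

    Dispersion = variance/mean of the de-logged normalized values, z-scored
    within ``n_bins`` equal-frequency bins of log mean expression, so highly
    expressed genes do not dominate purely through their means. Sets
    ``nm.hvg_flags`` and returns the boolean flags.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    x = np.expm1(nm.values) if nm.log_transformed else nm.values
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(nm.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    logmean = np.log1p(mean)
    # quantile bins on log mean; genes with equal means share a bin
    edges = np.unique(np.quantile(logmean, np.linspace(0, 1, n_bins + 1))[1:-1])
    bins = np.digitize(logmean, edges)
    norm_disp = np.zeros(nm.n_genes)
    for b in np.unique(bins):
        mask = bins == b
        mu_b = disp[mask].mean()
        sd_b = disp[mask].std()
        if sd_b > 0:
            norm_disp[mask] = (disp[mask] - mu_b) / sd_b
    n_sel = min(n_top, nm.n_genes)
    if n_top > nm.n_genes:
        logger.warning("n_top=%d exceeds %d genes; flagging all", n_top, nm.n_genes)
    ranked = np.argsort(-norm_disp, kind="stable")
    flags = np.zeros(nm.n_genes, dtype=bool)
    flags[ranked[:n_sel]] = True
    nm.hvg_flags = flags
    return flags


def scale_per_sample(
    nm: NormalizedMatrix, clip: float = 10.0, scope: str = "per_sample"
) -> NormalizedMatrix:
    """Standardize HVG columns to zero mean / unit variance within each sample.

    Constant genes (SD 0) are left at 0; samples with a single cell are
    mean-centered only (which also yields zeros) with a logged warning.
    Values are clipped at ``clip`` SDs. Non-HVG columns are untouched.
    """
    if nm.hvg_flags is None:
        raise ValueError("select_hvg must be called before scaling")
    values = nm.values.copy()
    hvg = nm.hvg_flags
    groups = (
        [np.ones(nm.n_cells, dtype=bool)]
        if scope == "global"
        else [nm.sample_of_cell == s for s in np.unique(nm.sample_of_cell.astype(str))]
    )
    for mask in groups:
        block = values[np.ix_(mask, hvg)]
        mu = block.mean(axis=0)
        if block.shape[0] < 2:
            logger.warning("sample with a single cell: mean-centering only")
            sd = np.ones(block.shape[1])
        else:
            sd = block.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        scaled = (block - mu) / sd
        np.clip(scaled, -clip, clip, out=scaled)
        values[np.ix_(mask, hvg)] = scaled
    return NormalizedMatrix(
        values=values,
        gene_ids=nm.gene_ids,
        cell_ids=nm.cell_ids,
        sample_of_cell=nm.sample_of_cell,
        per_cell_target=nm.per_cell_target,
        log_transformed=nm.log_transformed,
        hvg_flags=hvg.copy(),
        scaling_scope=scope,
        library_size=nm.library_size,
    )
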