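"""Synthetic snRNA-seq data with the statistical structure the pipeline assumes.

The generator draws UMI counts from a gamma-Poisson (negative binomial) model
with lognormal cell size factors. On top of that baseline it plants:

* cortical cell types with marker-gene programs (log-fold elevations),
* four microglial subtypes (homeostatic / motile / ARM / dystrophic) whose
  amyloid-responsive-microglia (ARM) membership follows a logistic model in
  the donor's AT score, APOE genotype and TREM2 genotype,
* multiplicative per-(gene, sample) batch effects,
* per-cell mitochondrial UMI fractions on ``MT-`` prefixed genes,
* doublets formed by summing the counts of two same-sample cells.

Everything is reproducible given ``SimulationDesign.seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"

# (name, proportion, marker genes, ln-fold marker elevation)
CellTypeSpec = tuple[str, float, tuple[str, ...], float]


def _program(prefix: str, n: int) -> tuple[str, ...]:
    """Synthetic program-gene names padding a type's expression signature.

    Real cell types differ across hundreds of genes, not just their
    canonical markers; each simulated type therefore carries its named
    markers plus ``n`` anonymous program genes at the same elevation.
    """
    return tuple(f"{prefix}-PRG{i + 1:02d}" for i in range(n))


#: Default cortical cell-type composition: oligodendrocytes and excitatory
#: neurons dominate, microglia ~3% and endothelial cells <1% of nuclei, as is
#: typical for frontal-cortex single-nucleus data.
DEFAULT_CELL_TYPES: tuple[CellTypeSpec, ...] = (
    ("excitatory_neuron", 0.320,
     ("SLC17A7", "GRIN1", "GRIN2B", "SATB2", "RORB") + _program("EX", 25), 2.0),
    ("oligodendrocyte", 0.360,
     ("MBP", "MOG", "OLIG1", "PLP1", "MAG") + _program("OLI", 25), 2.0),
    ("astrocyte", 0.128,
     ("AQP4", "GFAP", "SLC1A2", "ALDH1L1", "GJA1") + _program("AST", 25), 2.0),
    ("inhibitory_neuron", 0.100,
     ("GAD1", "GAD2", "SLC32A1", "PVALB", "SST") + _program("IN", 25), 2.0),
    ("opc", 0.056,
     ("PDGFRA", "CSPG4", "SOX10", "LHFPL3", "OLIG2") + _program("OPC", 25), 2.0),
    ("microglia", 0.032,
     ("CX3CR1", "C1QB", "CSF1R", "P2RY12", "TMEM119") + _program("MIC", 25), 2.0),
    ("endothelial", 0.004,
     ("CLDN5", "FLT1", "PECAM1", "VWF", "A2M") + _program("END", 25), 2.0),
)

#: Microglial subtype programs. Baseline proportions describe the reference
#: condition (A+T-, TREM2 WT, APOE E3/E3) in which the amyloid-responsive
#: population peaks; other conditions shift the ARM logit (see
#: ``DEFAULT_ARM_LOGIT_EFFECTS``).
DEFAULT_MICROGLIA_SUBTYPES: tuple[CellTypeSpec, ...] = (
    ("arm", 0.775,
     ("CD163", "SPP1", "C1QA", "FCGBP", "SLC11A1") + _program("ARM", 15), 1.5),
    ("homeostatic", 0.100,
     ("CX3CR1", "SELPLG", "MEF2A") + _program("HOM", 15), 1.5),
    ("motile", 0.090,
     ("FGD4", "ARHGAP15", "ARHGAP24", "BMP2K", "FOXP1") + _program("MOT", 15), 1.5),
    ("dystrophic", 0.035,
     ("FTL", "FTH1", "SKAP2") + _program("DYS", 15), 1.5),
)

#: Additive effects on the ARM-membership logit, relative to the reference
#: condition A+T- / APOE E3/E3 / TREM2 WT. Values are natural-log odds
#: ratios corresponding to the reductions observed across AT score, per
#: APOE E4 allele and for TREM2 R47H.
DEFAULT_ARM_LOGIT_EFFECTS: dict[str, float] = {
    "A-T-": math.log((0.078 / 0.922) / (0.775 / 0.225)),  # ~ -3.706
    "A+T+": math.log(0.101),
    "per_E4_allele": math.log(0.528),
    "R47H": math.log(0.509),
}

# 15-donor cohort: TREM2 WT with 2 A-T-, 4 A+T-, 5 A+T+, plus 4 R47H cases.
DEFAULT_AT_SCORES = (
    "A-T-", "A-T-",
    "A+T-", "A+T-", "A+T-", "A+T-",
    "A+T+", "A+T+", "A+T+", "A+T+", "A+T+",
    "A+T-", "A+T+", "A+T+", "A+T+",
)
DEFAULT_APOE = (
    "E3/E3", "E3/E3",
    "E3/E3", "E3/E3", "E3/E4", "E3/E4",
    "E3/E3", "E3/E4", "E3/E4", "E3/E4", "E4/E4",
    "E3/E3", "E3/E3", "E3/E4", "E3/E3",
)
DEFAULT_TREM2 = ("WT",) * 11 + ("R47H",) * 4


@dataclass
class SimulationDesign:
    """Parameters of one synthetic cohort.

    ``cell_type_table`` / ``microglia_subtype_table`` rows are
    ``(name, proportion, marker gene tuple, ln-fold marker elevation)``;
    proportions must each sum to 1. ``arm_logit_effects`` are additive
    shifts of the ARM-membership logit keyed by ``"A-T-"``, ``"A+T+"``,
    ``"per_E4_allele"`` and ``"R47H"``.
    """

    n_samples: int = 15
    cells_per_sample: int = 1000
    n_genes: int = 3000
    cell_type_table: tuple[CellTypeSpec, ...] = DEFAULT_CELL_TYPES
    microglia_subtype_table: tuple[CellTypeSpec, ...] = DEFAULT_MICROGLIA_SUBTYPES
    at_score_per_sample: tuple[str, ...] = DEFAULT_AT_SCORES
    apoe_per_sample: tuple[str, ...] = DEFAULT_APOE
    trem2_per_sample: tuple[str, ...] = DEFAULT_TREM2
    arm_logit_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARM_LOGIT_EFFECTS)
    )
    batch_effect_sd: float = 0.15
    mito_gene_fraction: float = 0.01
    mito_expr_fraction: float = 0.025
    doublet_rate: float = 0.01
    mean_library: float = 1200.0
    size_factor_sd: float = 0.35
    dispersion: float = 0.3
    microglia_type: str = "microglia"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("n_samples", self.n_samples),
            ("cells_per_sample", self.cells_per_sample),
            ("n_genes", self.n_genes),
        ):
            if val < 1:
                raise ValueError(f"{name} must be >= 1, got {val}")
        for name, val in (
            ("batch_effect_sd", self.batch_effect_sd),
            ("mean_library", self.mean_library),
            ("size_factor_sd", self.size_factor_sd),
            ("dispersion", self.dispersion),
        ):
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        for name, val in (
            ("mito_gene_fraction", self.mito_gene_fraction),
            ("mito_expr_fraction", self.mito_expr_fraction),
            ("doublet_rate", self.doublet_rate),
        ):
            if not np.isfinite(val) or not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {val}")
        for table, label in (
            (self.cell_type_table, "cell_type_table"),
            (self.microglia_subtype_table, "microglia_subtype_table"),
        ):
            props = np.array([row[1] for row in table], dtype=float)
            if np.any(~np.isfinite(props)) or np.any(props < 0) or np.any(props > 1):
                raise ValueError(f"{label} proportions must be finite and in [0, 1]")
            if abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(f"{label} proportions must sum to 1 (got {props.sum()})")
            effects = np.array([row[3] for row in table], dtype=float)
            if np.any(~np.isfinite(effects)):
                raise ValueError(f"{label} marker effects must be finite")
        if any(not np.isfinite(v) for v in self.arm_logit_effects.values()):
            raise ValueError("arm_logit_effects must be finite")
        for seq, label in (
            (self.at_score_per_sample, "at_score_per_sample"),
            (self.apoe_per_sample, "apoe_per_sample"),
            (self.trem2_per_sample, "trem2_per_sample"),
        ):
            if len(seq) < self.n_samples:
                raise ValueError(
                    f"{label} has {len(seq)} entries but n_samples={self.n_samples}"
                )


def default_design(**overrides) -> SimulationDesign:
    """The default synthetic cohort: 15 donors x 1,000 nuclei, 3,000 genes."""
    return SimulationDesign(**overrides)


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI counts with identifiers and sample labels."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_of_cell: np.ndarray
    mito_gene_flags: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        self.mito_gene_flags = np.asarray(self.mito_gene_flags, dtype=bool)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes or len(np.unique(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique and match the matrix width")
        if len(self.cell_ids) != n_cells or len(np.unique(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique and match the matrix height")
        if len(self.sample_of_cell) != n_cells:
            raise ValueError("sample_of_cell must have one entry per cell")
        if len(self.mito_gene_flags) != n_genes:
            raise ValueError("mito_gene_flags must have one entry per gene")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell mitochondrial UMI fraction (0 for empty cells)."""
        lib = self.library_sizes()
        mito = np.asarray(
            self.counts[:, self.mito_gene_flags].sum(axis=1)
        ).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
        return frac


@dataclass
class CaseMetadata:
    """Per-sample donor table: genotypes, AT score and demographics."""

    table: pd.DataFrame  # columns: sample_id, at_score, apoe, trem2, sex, age

    def __post_init__(self) -> None:
        required = {"sample_id", "at_score", "apoe", "trem2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")

    def lookup(self, column: str) -> dict[str, object]:
        return dict(zip(self.table["sample_id"], self.table[column]))


@dataclass
class TrueLabels:
    """Ground truth of a simulated cohort (per cell)."""

    cell_type: np.ndarray
    microglia_subtype: np.ndarray  # "" for non-microglia
    is_doublet: np.ndarray
    doublet_partner_type: np.ndarray  # "" for singlets


def _n_e4_alleles(apoe: str) -> int:
    return apoe.count("E4")


def arm_membership_probability(
    base_arm_prop: float,
    at_score: str,
    apoe: str,
    trem2: str,
    effects: dict[str, float],
) -> float:
    """ARM probability for a microglial cell under the logistic model.

    The baseline logit is ``logit(base_arm_prop)`` (reference condition
    A+T- / E3/E3 / WT); AT score, each APOE E4 allele and TREM2 R47H add
    their configured effects.
    """
    if base_arm_prop <= 0.0 or base_arm_prop >= 1.0:
        return float(np.clip(base_arm_prop, 0.0, 1.0))  # degenerate baseline
    logit = math.log(base_arm_prop / (1.0 - base_arm_prop))
    logit += effects.get(at_score, 0.0)
    logit += _n_e4_alleles(apoe) * effects.get("per_E4_allele", 0.0)
    if trem2 == "R47H":
        logit += effects.get("R47H", 0.0)
    return 1.0 / (1.0 + math.exp(-logit))


def assign_microglia_subtypes(
    n: int,
    subtype_table: tuple[CellTypeSpec, ...],
    arm_prob: float,
    rng: np.random.Generator,
    arm_name: str = "arm",
) -> np.ndarray:
    """Draw subtype labels for ``n`` microglial cells.

    ARM membership is Bernoulli(``arm_prob``); the remaining probability
    mass is split between the other subtypes in proportion to their
    baseline shares.
    """
    names = [row[0] for row in subtype_table]
    base = np.array([row[1] for row in subtype_table], dtype=float)
    probs = base.copy()
    arm_idx = names.index(arm_name)
    other = np.delete(base, arm_idx)
    probs[arm_idx] = arm_prob
    rest = np.delete(np.arange(len(names)), arm_idx)
    if other.sum() > 0:
        probs[rest] = (1.0 - arm_prob) * other / other.sum()
    else:
        probs[rest] = 0.0
    return rng.choice(np.array(names, dtype=object), size=n, p=probs)


def _gene_ids(design: SimulationDesign) -> tuple[np.ndarray, np.ndarray]:
    """Gene identifiers: named markers first, then MT- genes, then filler."""
    marker_names: list[str] = []
    for table in (design.cell_type_table, design.microglia_subtype_table):
        for _, _, markers, _ in table:
            for g in markers:
                if g not in marker_names:
                    marker_names.append(g)
    n_mito = int(round(design.mito_gene_fraction * design.n_genes))
    if len(marker_names) + n_mito > design.n_genes:
        raise ValueError("n_genes too small for the marker tables and mito genes")
    mito_names = [f"{MITO_PREFIX}SYN{i + 1}" for i in range(n_mito)]
    n_filler = design.n_genes - len(marker_names) - n_mito
    filler = [f"GENE{i + 1:05d}" for i in range(n_filler)]
    gene_ids = np.array(marker_names + mito_names + filler, dtype=object)
    mito_flags = np.array([g.startswith(MITO_PREFIX) for g in gene_ids], dtype=bool)
    return gene_ids, mito_flags


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[CountMatrix, TrueLabels, CaseMetadata]:
    """Simulate a cohort of UMI count matrices with planted structure.

    Counts are gamma-Poisson per gene with lognormal cell size factors;
    marker genes are elevated ``exp(effect)``-fold in their type/subtype;
    per-(gene, sample) batch effects are multiplicative with log-scale SD
    ``batch_effect_sd``; mitochondrial genes carry a per-cell fraction of
    the library; doublets are sums of two same-sample cells. Bit-reproducible
    given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    gene_ids, mito_flags = _gene_ids(design)
    n_genes = design.n_genes
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # baseline relative expression, lognormal across genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[mito_flags] = base[mito_flags].mean() if mito_flags.any() else 0.0

    type_names = [row[0] for row in design.cell_type_table]
    type_props = np.array([row[1] for row in design.cell_type_table])
    # per-type expression multipliers
    type_mult = {}
    for name, _, markers, effect in design.cell_type_table:
        mult = np.ones(n_genes)
        for g in markers:
            mult[gene_index[g]] = math.exp(effect)
        type_mult[name] = mult
    subtype_mult = {}
    for name, _, markers, effect in design.microglia_subtype_table:
        mult = np.ones(n_genes)
        for g in markers:
            mult[gene_index[g]] = math.exp(effect)
        subtype_mult[name] = mult

    sample_ids = [f"S{i + 1:02d}" for i in range(design.n_samples)]
    meta = CaseMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "at_score": list(design.at_score_per_sample[: design.n_samples]),
                "apoe": list(design.apoe_per_sample[: design.n_samples]),
                "trem2": list(design.trem2_per_sample[: design.n_samples]),
                "sex": ["M"] * design.n_samples,
                "age": rng.integers(65, 91, size=design.n_samples),
            }
        )
    )

    arm_base = dict(
        (row[0], row[1]) for row in design.microglia_subtype_table
    ).get("arm", 0.0)

    blocks: list[sp.csr_matrix] = []
    all_types: list[np.ndarray] = []
    all_subtypes: list[np.ndarray] = []
    all_doublet: list[np.ndarray] = []
    all_partner: list[np.ndarray] = []
    sample_labels: list[str] = []
    mito_idx = np.where(mito_flags)[0]
    non_mito_idx = np.where(~mito_flags)[0]

    for s in range(design.n_samples):
        n_cells = design.cells_per_sample
        at = design.at_score_per_sample[s]
        apoe = design.apoe_per_sample[s]
        trem2 = design.trem2_per_sample[s]

        batch = np.exp(rng.normal(0.0, design.batch_effect_sd, size=n_genes))
        cell_types = rng.choice(
            np.array(type_names, dtype=object), size=n_cells, p=type_props
        )
        subtypes = np.array([""] * n_cells, dtype=object)
        is_mic = cell_types == design.microglia_type
        if is_mic.any() and design.microglia_subtype_table:
            p_arm = arm_membership_probability(
                arm_base, at, apoe, trem2, design.arm_logit_effects
            )
            subtypes[is_mic] = assign_microglia_subtypes(
                int(is_mic.sum()), design.microglia_subtype_table, p_arm, rng
            )

        # expected expression per cell
        mu = np.empty((n_cells, n_genes))
        for i in range(n_cells):
            prof = base * type_mult[cell_types[i]]
            if subtypes[i]:
                prof = prof * subtype_mult[subtypes[i]]
            mu[i] = prof * batch
        # per-cell mito fraction on a Beta around mito_expr_fraction
        if mito_idx.size and design.mito_expr_fraction > 0:
            conc = 200.0
            f = rng.beta(
                design.mito_expr_fraction * conc,
                (1.0 - design.mito_expr_fraction) * conc,
                size=n_cells,
            )
            non_mito_sum = mu[:, non_mito_idx].sum(axis=1)
            mito_sum = np.maximum(mu[:, mito_idx].sum(axis=1), 1e-300)
            mu[:, mito_idx] *= ((f / (1.0 - f)) * non_mito_sum / mito_sum)[:, None]
        mu /= mu.sum(axis=1, keepdims=True)
        lib = design.mean_library * rng.lognormal(
            -0.5 * design.size_factor_sd**2, design.size_factor_sd, size=n_cells
        )
        mu *= lib[:, None]

        if design.dispersion > 0:
            shape = 1.0 / design.dispersion
            lam = rng.gamma(shape, mu * design.dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(np.int32)

        # doublets: last cells of the sample absorb a random partner's counts
        n_doub = int(round(design.doublet_rate * n_cells))
        doublet = np.zeros(n_cells, dtype=bool)
        partner_type = np.array([""] * n_cells, dtype=object)
        if n_doub > 0 and n_cells > 1:
            doub_idx = np.arange(n_cells - n_doub, n_cells)
            for i in doub_idx:
                j = int(rng.integers(0, n_cells - n_doub))
                counts[i] += counts[j]
                doublet[i] = True
                partner_type[i] = cell_types[j]

        blocks.append(sp.csr_matrix(counts))
        all_types.append(cell_types)
        all_subtypes.append(subtypes)
        all_doublet.append(doublet)
        all_partner.append(partner_type)
        sample_labels.extend([sample_ids[s]] * n_cells)

    counts = sp.vstack(blocks, format="csr")
    n_total = counts.shape[0]
    cell_ids = np.array(
        [f"{sample_labels[i]}_C{i + 1:06d}" for i in range(n_total)], dtype=object
    )
    cm = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        sample_of_cell=np.array(sample_labels, dtype=object),
        mito_gene_flags=mito_flags,
    )
    truth = TrueLabels(
        cell_type=np.concatenate(all_types),
        microglia_subtype=np.concatenate(all_subtypes),
        is_doublet=np.concatenate(all_doublet),
        doublet_partner_type=np.concatenate(all_partner),
    )
    logger.info(
        "simulated %d cells x %d genes across %d samples (%d doublets)",
        n_total, n_genes, design.n_samples, int(truth.is_doublet.sum()),
    )
    return cm, truth, meta


# ---------------------------------------------------------------------------
# deterministic small fixture with hand-planted QC violations
# ---------------------------------------------------------------------------

FIXTURE_N_CELLS = 300
FIXTURE_N_GENES = 500
FIXTURE_N_MITO = 25
FIXTURE_N_SAMPLES = 3
#: Planted QC violations (disjoint cell index ranges):
FIXTURE_LOW_GENE_CELLS = range(0, 12)  # 12 cells with 150 expressed genes (< 200)
FIXTURE_HIGH_GENE_CELLS = range(12, 17)  # 5 cells with 450 expressed genes (> 400)
FIXTURE_HIGH_MITO_CELLS = range(17, 25)  # 8 cells with ~10% mito UMI (> 5%)
FIXTURE_GENE_CEILING = 400  # the fixture's own ceiling; 500 total genes
FIXTURE_RARE_GENES = range(475, 490)  # 15 genes expressed in exactly 5 cells (< 10)
FIXTURE_KEPT_RARE_GENES = range(490, 495)  # 5 genes expressed in exactly 12 cells


def fixture_small() -> tuple[CountMatrix, CaseMetadata]:
    """Deterministic ~300-cell, 500-gene fixture with planted QC violations.

    Planted, mutually disjoint violations (for a gene interval of
    [200, ``FIXTURE_GENE_CEILING``] and a 5% mito cap):

    * cells 0-11 (12 cells) express 150 genes — below the 200-gene floor;
    * cells 12-16 (5 cells) express 450 genes — above the fixture's
      400-gene ceiling (the matrix has only 500 genes, so the conventional
      4,000-gene ceiling is exercised on constructed matrices in tests);
    * cells 17-24 (8 cells) carry ~10% mitochondrial UMI — above the 5% cap;
    * genes 475-489 (15 genes) are expressed in exactly 5 cells (dropped by
      the 10-cell gene floor) and genes 490-494 in exactly 12 cells (kept).

    All other cells express ~250 genes with <1% mito fraction. The fixture
    is byte-identical across calls.
    """
    rng = np.random.default_rng(20200825)
    n_cells, n_genes = FIXTURE_N_CELLS, FIXTURE_N_GENES
    gene_ids = np.array(
        [f"{MITO_PREFIX}SYN{i + 1}" for i in range(FIXTURE_N_MITO)]
        + [f"GENE{i + 1:04d}" for i in range(n_genes - FIXTURE_N_MITO)],
        dtype=object,
    )
    mito_flags = np.array([g.startswith(MITO_PREFIX) for g in gene_ids], dtype=bool)
    reserved = set(FIXTURE_RARE_GENES) | set(FIXTURE_KEPT_RARE_GENES)
    # pool of ordinary genes: non-mito, non-reserved
    pool = np.array(
        [g for g in range(n_genes) if g >= FIXTURE_N_MITO and g not in reserved]
    )
    mito_pool = np.arange(FIXTURE_N_MITO)

    counts = np.zeros((n_cells, n_genes), dtype=np.int32)
    for i in range(n_cells):
        if i in FIXTURE_LOW_GENE_CELLS:
            n_expr = 150
        elif i in FIXTURE_HIGH_GENE_CELLS:
            n_expr = 450
        else:
            n_expr = 250
        if i in FIXTURE_HIGH_MITO_CELLS:
            chosen = rng.choice(pool, size=n_expr - 5, replace=False)
            counts[i, chosen] = rng.integers(1, 4, size=chosen.size)
            mito_genes = rng.choice(mito_pool, size=5, replace=False)
            # ~10% of the library on mito genes
            total = counts[i].sum()
            counts[i, mito_genes] = max(1, int(round(total / 9.0 / 5.0)))
        else:
            if n_expr > pool.size:
                chosen = rng.choice(
                    np.concatenate([pool, mito_pool]), size=n_expr, replace=False
                )
            else:
                chosen = rng.choice(pool, size=n_expr - 2, replace=False)
                chosen = np.concatenate(
                    [chosen, rng.choice(mito_pool, size=2, replace=False)]
                )
            counts[i, chosen] = rng.integers(1, 4, size=chosen.size)

    # rare genes planted in known QC-survivor cells (indices >= 25 pass all
    # cell filters by construction)
    for k, g in enumerate(FIXTURE_RARE_GENES):
        cells = 25 + 5 * k + np.arange(5)
        counts[cells, g] = 1
    for k, g in enumerate(FIXTURE_KEPT_RARE_GENES):
        cells = 120 + 12 * k + np.arange(12)
        counts[cells, g] = 1

    per_sample = n_cells // FIXTURE_N_SAMPLES
    samples = np.array(
        [f"FS{i // per_sample + 1}" for i in range(n_cells)], dtype=object
    )
    cell_ids = np.array([f"FIX_C{i + 1:04d}" for i in range(n_cells)], dtype=object)
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        sample_of_cell=samples,
        mito_gene_flags=mito_flags,
    )
    meta = CaseMetadata(
        pd.DataFrame(
            {
                "sample_id": ["FS1", "FS2", "FS3"],
                "at_score": ["A-T-", "A+T-", "A+T+"],
                "apoe": ["E3/E3", "E3/E4", "E4/E4"],
                "trem2": ["WT", "WT", "R47H"],
                "sex": ["M", "M", "M"],
                "age": [70, 75, 80],
            }
        )
    )
    return cm, meta
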