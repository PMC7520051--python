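"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes QC -> normalization -> multi-resolution clustering
-> consensus annotation -> batch-mixing diagnostics -> microglia
subclustering and contamination removal -> differential expression (both
modes) -> proportion statistics -> metacells -> cell-specific networks ->
pairwise energy tests, writing TSV/JSON artifacts plus a run manifest with
config hash and per-file checksums. Each stage checkpoints its state so
``resume=True`` regenerates only the stages downstream of a missing
checkpoint.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from armnet import __version__
from armnet.clustering import (
    ConsensusRule,
    MICROGLIA_SUBTYPE_MARKERS,
    UNANNOTATED,
    annotate_clusters,
    cluster_multiresolution,
    consensus_annotate,
    flag_contaminant_subclusters,
    marker_scores,
)
from armnet.config import PipelineConfig
from armnet.csn import csn_all, vectorize_csns
from armnet.de import de_wilcoxon, select_genes_anova
from armnet.energy import pairwise_subtype_tests
from armnet.io_utils import read_metadata, read_mtx, write_tsv
from armnet.metacell import build_metacells, gene_filter_expression_rate
from armnet.mixing import BatchMixingConfig, kl_batch_mixing
from armnet.qc import filter_cells_genes, normalize_log, scale_per_sample, select_hvg
from armnet.simulate import CountMatrix, default_design, simulate_dataset
from armnet.stats import cross_tab, cross_tab_or

logger = logging.getLogger(__name__)

STAGES = (
    "load",
    "qc",
    "preprocess",
    "cluster",
    "annotate",
    "mixing",
    "microglia",
    "de",
    "proportions",
    "networks",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {
                str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
                for p in outputs
            },
        }

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "seed": self.seed,
                    "stages": self.stages,
                },
                indent=2,
            )
        )


def _checkpoint_path(outdir: Path, stage: str) -> Path:
    return outdir / "checkpoints" / f"{stage}.pkl"


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> RunManifest:
    """Run every stage; returns the manifest (also written to disk).

    Any stage error halts the run with the stage name; already-written
    partial outputs and checkpoints stay on disk. With ``resume=True``,
    stages whose checkpoints exist are reloaded instead of recomputed.
    """
    outdir = Path(cfg.output_dir)
    (outdir / "checkpoints").mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.config_hash(), version=__version__, seed=cfg.seed
    )
    ctx: dict = {}
    can_resume = resume
    for stage in STAGES:
        ckpt = _checkpoint_path(outdir, stage)
        if can_resume and ckpt.exists():
            with open(ckpt, "rb") as fh:
                saved = pickle.load(fh)
            if all(Path(p).exists() for p in saved["outputs"]):
                ctx = saved["ctx"]
                logger.info("stage %s: resumed from checkpoint", stage)
                manifest.stages[stage] = {"resumed": True}
                continue
            # a deleted output invalidates this stage and everything after
            can_resume = False
        else:
            can_resume = False
        try:
            outputs = _STAGE_FUNCS[stage](cfg, ctx, outdir)
        except Exception as exc:
            manifest.write(outdir / "manifest.json")
            raise StageError(stage, exc) from exc
        with open(ckpt, "wb") as fh:
            pickle.dump({"ctx": ctx, "outputs": [str(p) for p in outputs]}, fh)
        manifest.record(stage, outputs)
        logger.info("stage %s: done (%d outputs)", stage, len(outputs))
    manifest.write(outdir / "manifest.json")
    return manifest


def _stage_load(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    if cfg.input_mtx_dir:
        cm = read_mtx(cfg.input_mtx_dir)
        meta = read_metadata(cfg.input_metadata) if cfg.input_metadata else None
        truth = None
    else:
        design = default_design(
            seed=cfg.stage_seed("simulate"), **cfg.simulate_overrides
        )
        cm, truth, meta = simulate_dataset(design)
    ctx.update(cm=cm, meta=meta, truth=truth)
    return []


def _stage_qc(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    cm, report = filter_cells_genes(ctx["cm"], cfg.qc)
    keep = np.isin(ctx["cm"].cell_ids, cm.cell_ids)
    if ctx["truth"] is not None:
        t = ctx["truth"]
        ctx["truth_qc"] = {
            "cell_type": t.cell_type[keep],
            "microglia_subtype": t.microglia_subtype[keep],
            "is_doublet": t.is_doublet[keep],
            "doublet_partner_type": t.doublet_partner_type[keep],
        }
    ctx["cm_qc"] = cm
    path = outdir / "qc_report.json"
    path.write_text(json.dumps(report.to_dict(), indent=2))
    return [path]


def _stage_preprocess(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    nm = normalize_log(ctx["cm_qc"], target=cfg.preprocess.target)
    select_hvg(nm, cfg.preprocess.n_hvg)
    ctx["nm_log"] = nm
    ctx["nm_scaled"] = scale_per_sample(nm, clip=cfg.preprocess.clip)
    return []


def _stage_cluster(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    mrl = cluster_multiresolution(
        ctx["nm_scaled"],
        resolutions=cfg.clustering.resolutions,
        backend=cfg.clustering.backend,
        seed=cfg.stage_seed("cluster"),
        n_pcs=cfg.clustering.n_pcs,
        n_neighbors=cfg.clustering.n_neighbors,
    )
    ctx["mrl"] = mrl
    df = pd.DataFrame(
        mrl.labels, columns=[f"res_{r:g}" for r in mrl.resolutions]
    )
    df.insert(0, "cell_id", ctx["cm_qc"].cell_ids)
    return [write_tsv(df, outdir / "cluster_labels.tsv")]


def _stage_annotate(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    maps = annotate_clusters(ctx["mrl"], ctx["nm_scaled"])
    rule = ConsensusRule(n_resolutions=len(ctx["mrl"].resolutions))
    labels = consensus_annotate(ctx["mrl"], maps, rule)
    ctx["cell_type"] = labels
    df = pd.DataFrame({"cell_id": ctx["cm_qc"].cell_ids, "cell_type": labels})
    return [write_tsv(df, outdir / "cell_types.tsv")]


def _stage_mixing(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    bc = BatchMixingConfig(
        N=cfg.mixing.N,
        K=min(cfg.mixing.K, ctx["mrl"].n_cells - 1),
        space="embedding",
        seed=cfg.stage_seed("mixing"),
    )
    res = kl_batch_mixing(
        ctx["mrl"].embedding, ctx["cm_qc"].sample_of_cell, bc
    )
    path = outdir / "batch_mixing.json"
    path.write_text(json.dumps(res.to_dict(), indent=2))
    ctx["mixing"] = res
    return [path]


def _stage_microglia(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    """Subcluster microglia, name subtypes by marker programs, drop contaminants."""
    mask = ctx["cell_type"] == cfg.microglia_type
    if ctx["truth"] is not None:
        # contaminating doublets with a microglial component end up in the
        # microglial pool, as in real data
        t = ctx["truth_qc"]
        mask = mask | (
            t["is_doublet"]
            & (
                (t["cell_type"] == cfg.microglia_type)
                | (t["doublet_partner_type"] == cfg.microglia_type)
            )
        )
    if mask.sum() < cfg.clustering.n_neighbors + 2:
        raise ValueError(f"too few microglia to subcluster ({int(mask.sum())})")
    nm_mic = ctx["nm_log"].subset_cells(mask)
    select_hvg(nm_mic, cfg.preprocess.n_hvg_microglia)
    nm_mic_scaled = scale_per_sample(
        nm_mic, clip=cfg.preprocess.clip, scope=cfg.preprocess.microglia_scale_scope
    )
    mrl = cluster_multiresolution(
        nm_mic_scaled,
        resolutions=(cfg.clustering.microglia_resolution,),
        backend=cfg.clustering.backend,
        seed=cfg.stage_seed("microglia"),
        n_pcs=cfg.clustering.microglia_n_pcs,
        n_neighbors=min(cfg.clustering.n_neighbors, int(mask.sum()) - 2),
    )
    sub = mrl.labels[:, 0]
    flags = flag_contaminant_subclusters(
        sub, nm_mic_scaled, microglia_type=cfg.microglia_type
    )
    keep = np.array([not flags[int(c)] for c in sub])
    # name kept subclusters by their best-scoring subtype marker program
    scores, names = marker_scores(nm_mic, MICROGLIA_SUBTYPE_MARKERS)
    subtype = np.array([UNANNOTATED] * len(sub), dtype=object)
    for c in np.unique(sub):
        cmask = sub == c
        if flags[int(c)]:
            subtype[cmask] = "contaminant"
            continue
        mean_scores = np.nanmean(scores[cmask], axis=0)
        subtype[cmask] = names[int(np.nanargmax(mean_scores))]
    ctx["mic_mask"] = mask
    ctx["mic_keep"] = keep
    ctx["mic_subtype"] = subtype
    ctx["nm_mic"] = nm_mic
    df = pd.DataFrame(
        {
            "cell_id": nm_mic.cell_ids,
            "subcluster": sub,
            "subtype": subtype,
            "contaminant": ~keep,
        }
    )
    return [write_tsv(df, outdir / "microglia_subtypes.tsv")]


def _stage_de(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    keep = ctx["mic_keep"]
    nm = ctx["nm_mic"].subset_cells(keep)
    groups = ctx["mic_subtype"][keep]
    outputs = []
    frames = []
    for mode in ("one_vs_rest", "one_vs_homeostatic"):
        frames.append(
            de_wilcoxon(
                nm, groups, mode=mode,
                min_cells=cfg.de.min_cells, alpha=cfg.de.alpha,
                log2fc_threshold=cfg.de.log2fc_threshold,
            )
        )
    de = pd.concat(frames, ignore_index=True)
    ctx["de"] = de
    outputs.append(write_tsv(de[de["significant"]], outdir / "de_significant.tsv"))
    outputs.append(write_tsv(de, outdir / "de_all.tsv"))
    return outputs


def _stage_proportions(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    keep = ctx["mic_keep"]
    nm = ctx["nm_mic"]
    subtype = ctx["mic_subtype"][keep]
    samples = nm.sample_of_cell[keep]
    meta = ctx["meta"]
    rows = []
    if meta is not None:
        for column, conds in (
            ("at_score", [("A+T-", "A-T-"), ("A+T+", "A+T-")]),
            ("apoe", [("E3/E4", "E3/E3"), ("E4/E4", "E3/E3")]),
            ("trem2", [("R47H", "WT")]),
        ):
            lookup = meta.lookup(column)
            cond = np.array([str(lookup.get(s, "NA")) for s in samples], dtype=object)
            for c1, c2 in conds:
                present = set(np.unique(cond))
                if c1 not in present or c2 not in present:
                    continue
                tab = cross_tab(subtype, cond, "arm", c1, c2)
                try:
                    res = cross_tab_or(tab)
                except ValueError:
                    continue
                rows.append(
                    {
                        "grouping": column, "cond1": c1, "cond2": c2,
                        "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                        "odds_ratio": res.or_point,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "p_fisher": res.p_fisher,
                    }
                )
    df = pd.DataFrame(rows)
    ctx["proportions"] = df
    return [write_tsv(df, outdir / "arm_proportions.tsv")]


def _stage_networks(cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    keep = ctx["mic_keep"]
    cm_mic_counts = ctx["cm_qc"].counts[ctx["mic_mask"]][keep]
    cm_mic = CountMatrix(
        counts=cm_mic_counts,
        gene_ids=ctx["cm_qc"].gene_ids,
        cell_ids=ctx["nm_mic"].cell_ids[keep],
        sample_of_cell=ctx["nm_mic"].sample_of_cell[keep],
        mito_gene_flags=ctx["cm_qc"].mito_gene_flags,
    )
    gene_mask = gene_filter_expression_rate(cm_mic, cfg.csn.min_expression_rate)
    nm = ctx["nm_mic"].subset_cells(keep)
    nm_f = nm  # values restricted below
    values = nm.values[:, gene_mask]
    from armnet.qc import NormalizedMatrix  # local import to avoid cycle noise

    nm_f = NormalizedMatrix(
        values=values,
        gene_ids=nm.gene_ids[gene_mask],
        cell_ids=nm.cell_ids,
        sample_of_cell=nm.sample_of_cell,
        per_cell_target=nm.per_cell_target,
        log_transformed=nm.log_transformed,
        library_size=nm.library_size,
    )
    subtype = ctx["mic_subtype"][keep]
    mcs = build_metacells(
        nm_f,
        subject_of_cell=nm_f.sample_of_cell,
        subtype_of_cell=subtype,
        target_size=cfg.csn.target_size,
        min_library=cfg.csn.min_library,
        seed=cfg.stage_seed("metacell"),
    )
    st_names, st_counts = np.unique(mcs.subtype_of_metacell, return_counts=True)
    usable = set(st_names[st_counts >= 2])
    anova_mask = np.array([s in usable for s in mcs.subtype_of_metacell])
    if len(usable) >= 2:
        anova_idx = select_genes_anova(
            mcs.expr[anova_mask], mcs.subtype_of_metacell[anova_mask],
            n_select=min(cfg.de.n_anova_genes, nm_f.n_genes),
        )
    else:
        anova_idx = np.arange(min(cfg.de.n_anova_genes, nm_f.n_genes))
    outputs = []
    mc_df = pd.DataFrame(
        {
            "cell_id": nm_f.cell_ids[mcs.cell_index],
            "metacell": mcs.assignment,
        }
    )
    outputs.append(write_tsv(mc_df, outdir / "metacell_assignment.tsv"))
    ctx["metacells"] = mcs
    from armnet.csn import MIN_POOL

    if mcs.n_metacells < MIN_POOL:
        logger.warning(
            "only %d metacells (< %d): skipping CSN/energy analysis",
            mcs.n_metacells, MIN_POOL,
        )
        return outputs
    pool = mcs.expr[:, anova_idx]
    csns = csn_all(
        pool,
        alpha_edge=cfg.csn.alpha_edge,
        h=cfg.csn.h,
        neighborhood_frac=cfg.csn.neighborhood_frac,
        gene_ids=nm_f.gene_ids[anova_idx],
    )
    vectors = vectorize_csns(csns)
    by_subtype = {
        name: vectors[mcs.subtype_of_metacell == name]
        for name in np.unique(mcs.subtype_of_metacell)
        if (mcs.subtype_of_metacell == name).sum() >= 2
    }
    if len(by_subtype) >= 2:
        pmat = pairwise_subtype_tests(
            by_subtype,
            alpha=cfg.energy.alpha,
            n_perm=cfg.energy.n_perm,
            seed=cfg.stage_seed("energy"),
        )
        ctx["energy_p"] = pmat
        outputs.append(
            write_tsv(pmat.reset_index(names="subtype"), outdir / "energy_pvalues.tsv")
        )
    return outputs


_STAGE_FUNCS = {
    "load": _stage_load,
    "qc": _stage_qc,
    "preprocess": _stage_preprocess,
    "cluster": _stage_cluster,
    "annotate": _stage_annotate,
    "mixing": _stage_mixing,
    "microglia": _stage_microglia,
    "de": _stage_de,
    "proportions": _stage_proportions,
    "networks": _stage_networks,
}
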