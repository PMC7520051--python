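"""Multi-resolution clustering, annotation, consensus and contamination flags."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from armnet.clustering import (
    ConsensusRule,
    DEFAULT_RESOLUTIONS,
    MultiResolutionLabels,
    UNANNOTATED,
    annotate_clusters,
    cluster_multiresolution,
    consensus_annotate,
    flag_contaminant_subclusters,
)
from armnet.qc import NormalizedMatrix, filter_cells_genes, normalize_log, scale_per_sample, select_hvg
from armnet.simulate import CountMatrix, default_design, simulate_dataset


def _nm(values, gene_ids=None, samples=None, hvg=True):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=values,
        gene_ids=np.array(
            gene_ids if gene_ids is not None else [f"G{i}" for i in range(n_genes)],
            dtype=object,
        ),
        cell_ids=np.array([f"C{i}" for i in range(n_cells)], dtype=object),
        sample_of_cell=np.array(
            samples if samples is not None else ["S1"] * n_cells, dtype=object
        ),
        log_transformed=True,
        hvg_flags=np.ones(n_genes, dtype=bool) if hvg else None,
    )


@pytest.fixture(scope="module")
def three_type_data():
    """Well-separated 3-type cohort for recovery tests."""
    def prg(p, n=20):
        return tuple(f"{p}-PRG{i + 1:02d}" for i in range(n))

    types = (
        ("microglia", 0.3,
         ("CX3CR1", "C1QB", "CSF1R", "P2RY12", "TMEM119") + prg("MIC"), 2.5),
        ("astrocyte", 0.4,
         ("AQP4", "GFAP", "SLC1A2", "ALDH1L1", "GJA1") + prg("AST"), 2.5),
        ("oligodendrocyte", 0.3,
         ("MBP", "MOG", "OLIG1", "PLP1", "MAG") + prg("OLI"), 2.5),
    )
    design = default_design(
        n_samples=2,
        cells_per_sample=300,
        n_genes=600,
        cell_type_table=types,
        microglia_subtype_table=(("arm", 1.0, ("CD163",), 0.0),),
        doublet_rate=0.0,
        seed=21,
    )
    cm, truth, _ = simulate_dataset(design)
    cm_qc, _ = filter_cells_genes(cm)
    keep = np.isin(cm.cell_ids, cm_qc.cell_ids)
    nm = normalize_log(cm_qc)
    select_hvg(nm, 300)
    scaled = scale_per_sample(nm)
    return scaled, truth.cell_type[keep]


class TestClusterMultiresolution:
    @pytest.mark.parametrize("backend", ["leiden", "louvain"])
    def test_recovers_planted_types_at_every_resolution(self, three_type_data, backend):
        scaled, truth = three_type_data
        mrl = cluster_multiresolution(scaled, backend=backend, seed=0)
        for j in range(len(mrl.resolutions)):
            ari = adjusted_rand_score(truth, mrl.labels[:, j])
            assert ari >= 0.9, (backend, mrl.resolutions[j], ari)

    def test_deterministic_given_seed(self, three_type_data):
        scaled, _ = three_type_data
        a = cluster_multiresolution(scaled, resolutions=(0.4,), seed=7)
        b = cluster_multiresolution(scaled, resolutions=(0.4,), seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_duplicate_cells_get_identical_labels(self, three_type_data):
        scaled, _ = three_type_data
        dup = NormalizedMatrix(
            values=np.vstack([scaled.values, scaled.values[:1]]),
            gene_ids=scaled.gene_ids,
            cell_ids=np.append(scaled.cell_ids, "DUP"),
            sample_of_cell=np.append(scaled.sample_of_cell, scaled.sample_of_cell[0]),
            log_transformed=True,
            hvg_flags=scaled.hvg_flags,
        )
        mrl = cluster_multiresolution(dup, seed=0)
        assert np.array_equal(mrl.labels[0], mrl.labels[-1])

    def test_single_resolution_gives_one_column(self, three_type_data):
        scaled, _ = three_type_data
        mrl = cluster_multiresolution(scaled, resolutions=(0.3,), seed=0)
        assert mrl.labels.shape[1] == 1
        assert mrl.max_prob.shape == mrl.labels.shape
        assert np.all(mrl.max_prob == 1.0)

    def test_too_few_cells_raises(self):
        nm = _nm(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError):
            cluster_multiresolution(nm, n_neighbors=15)


class TestAnnotate:
    def test_pure_clusters_annotated_correctly(self, three_type_data):
        scaled, truth = three_type_data
        mrl = cluster_multiresolution(scaled, seed=0)
        maps = annotate_clusters(mrl, scaled)
        labels = consensus_annotate(mrl, maps)
        acc = np.mean(labels == truth)
        assert acc >= 0.95

    def test_absent_marker_set_never_assigned(self):
        rng = np.random.default_rng(0)
        nm = _nm(rng.normal(size=(50, 4)), gene_ids=["A", "B", "C", "D"])
        mrl = MultiResolutionLabels(
            resolutions=(0.1,),
            labels=np.zeros((50, 1), dtype=int),
            max_prob=np.ones((50, 1)),
            embedding=nm.values,
        )
        maps = annotate_clusters(
            mrl, nm, markers={"ghost": frozenset({"ZZZ"}), "real": frozenset({"A"})}
        )
        assert maps[0][0][0] in ("real", None)

    def test_exact_tie_left_unassigned(self):
        values = np.zeros((30, 2))
        values[:15] = [3.0, 3.0]  # both markers identical -> tied scores
        nm = _nm(values, gene_ids=["M1", "M2"])
        mrl = MultiResolutionLabels(
            resolutions=(0.1,),
            labels=np.repeat([0, 1], 15)[:, None],
            max_prob=np.ones((30, 1)),
            embedding=values,
        )
        maps = annotate_clusters(
            mrl, nm, markers={"t1": frozenset({"M1"}), "t2": frozenset({"M2"})}
        )
        assert maps[0][0] == (None, pytest.approx(0.0, abs=1e-9))


class TestConsensus:
    def _mrl(self, votes):
        """Build labels where cluster id == vote index per resolution."""
        n_res = len(votes[0])
        labels = np.array([[i] * n_res for i in range(len(votes))])
        # give every cell its own cluster per resolution; map below
        return MultiResolutionLabels(
            resolutions=tuple(0.1 + 0.05 * j for j in range(n_res)),
            labels=labels,
            max_prob=np.ones_like(labels, dtype=float),
            embedding=np.zeros((len(votes), 2)),
        ), [
            {i: (votes[i][j], 1.0) for i in range(len(votes))}
            for j in range(n_res)
        ]

    def test_full_agreement_required_by_default(self):
        votes = [
            ["microglia"] * 15,
            ["astrocyte"] * 14 + ["oligodendrocyte"],
            ["endothelial"] * 14 + ["oligodendrocyte"],
            ["opc"] * 13 + ["oligodendrocyte"] * 2,
        ]
        mrl, maps = self._mrl(votes)
        out = consensus_annotate(mrl, maps, ConsensusRule(n_resolutions=15))
        assert list(out) == ["microglia", UNANNOTATED, "endothelial", UNANNOTATED]

    def test_order_invariance(self):
        votes = [["microglia"] * 7 + ["astrocyte"] * 8]
        mrl, maps = self._mrl(votes)
        rule = ConsensusRule(n_resolutions=15, relaxed_types=frozenset())
        out1 = consensus_annotate(mrl, maps, rule)
        out2 = consensus_annotate(mrl, maps[::-1], rule)
        assert np.array_equal(out1, out2)

    def test_unannotated_fraction_monotone_in_required_agreement(self, three_type_data):
        scaled, _ = three_type_data
        mrl = cluster_multiresolution(scaled, seed=0)
        maps = annotate_clusters(mrl, scaled)
        fracs = []
        for relax in (0, 3, 6, 9):
            rule = ConsensusRule(
                n_resolutions=15,
                relaxed_types=frozenset(
                    {"microglia", "astrocyte", "oligodendrocyte"}
                ),
                relaxation=relax,
            )
            out = consensus_annotate(mrl, maps, rule)
            fracs.append(np.mean(out == UNANNOTATED))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_annotated_proportions_match_design(self, three_type_data):
        scaled, truth = three_type_data
        mrl = cluster_multiresolution(scaled, seed=0)
        labels = consensus_annotate(mrl, annotate_clusters(mrl, scaled))
        for t, p in (("microglia", 0.3), ("astrocyte", 0.4), ("oligodendrocyte", 0.3)):
            se = np.sqrt(p * (1 - p) / len(labels))
            assert abs(np.mean(labels == t) - p) < 5 * se


class TestContaminantFlags:
    @pytest.fixture(scope="class")
    def microglia_pool(self):
        """Microglia plus a planted cluster of microglia+oligodendrocyte doublets."""
        design = default_design(
            n_samples=4, cells_per_sample=900, n_genes=1200, doublet_rate=0.0, seed=31
        )
        cm, truth, _ = simulate_dataset(design)
        cm_qc, _ = filter_cells_genes(cm)
        keep = np.isin(cm.cell_ids, cm_qc.cell_ids)
        tt = truth.cell_type[keep]
        st = truth.microglia_subtype[keep]
        rng = np.random.default_rng(0)
        mic_idx = np.where(tt == "microglia")[0]
        oli_idx = np.where(tt == "oligodendrocyte")[0]
        n_doub = 40
        di = rng.choice(mic_idx, n_doub, replace=False)
        dj = rng.choice(oli_idx, n_doub, replace=False)
        doub = cm_qc.counts[di].toarray() + cm_qc.counts[dj].toarray()
        pool = CountMatrix(
            counts=sp.vstack([cm_qc.counts[mic_idx], sp.csr_matrix(doub)]),
            gene_ids=cm_qc.gene_ids,
            cell_ids=np.array(
                [f"P{i}" for i in range(mic_idx.size + n_doub)], dtype=object
            ),
            sample_of_cell=np.concatenate(
                [cm_qc.sample_of_cell[mic_idx], cm_qc.sample_of_cell[di]]
            ),
            mito_gene_flags=cm_qc.mito_gene_flags,
        )
        nm = normalize_log(pool)
        select_hvg(nm, 500)
        scaled = scale_per_sample(nm, scope="global")
        mrl = cluster_multiresolution(scaled, resolutions=(2.0,), seed=0, n_pcs=20)
        sub = mrl.labels[:, 0]
        is_doub = np.arange(pool.n_cells) >= mic_idx.size
        return sub, scaled, is_doub, st[mic_idx]

    def test_planted_doublet_clusters_flagged(self, microglia_pool):
        sub, scaled, is_doub, _ = microglia_pool
        flags = flag_contaminant_subclusters(sub, scaled)
        doublet_clusters = [
            c for c in np.unique(sub) if np.mean(is_doub[sub == c]) > 0.5
        ]
        assert doublet_clusters, "no doublet-majority cluster formed"
        for c in doublet_clusters:
            assert flags[int(c)], f"doublet cluster {c} not flagged"

    def test_pure_subclusters_not_flagged(self, microglia_pool):
        sub, scaled, is_doub, _ = microglia_pool
        flags = flag_contaminant_subclusters(sub, scaled)
        for c in np.unique(sub):
            if np.mean(is_doub[sub == c]) < 0.2:
                assert not flags[int(c)], f"pure cluster {c} wrongly flagged"

    def test_empty_marker_table_flags_nothing(self, microglia_pool):
        sub, scaled, _, _ = microglia_pool
        flags = flag_contaminant_subclusters(sub, scaled, markers={})
        assert not any(flags.values())
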