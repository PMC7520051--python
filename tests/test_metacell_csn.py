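"""Metacell aggregation and cell-specific network construction."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from armnet.csn import average_adjacency, csn_all, csn_one, vectorize_csns
from armnet.metacell import build_metacells, gene_filter_expression_rate
from armnet.qc import NormalizedMatrix, filter_cells_genes, normalize_log
from armnet.simulate import CountMatrix, default_design, fixture_small, simulate_dataset


def _nm(values, samples=None, lib=None):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=values,
        gene_ids=np.array([f"G{i}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array([f"C{i}" for i in range(n_cells)], dtype=object),
        sample_of_cell=np.array(
            samples if samples is not None else ["S1"] * n_cells, dtype=object
        ),
        log_transformed=True,
        library_size=np.asarray(
            lib if lib is not None else np.full(n_cells, 1000.0)
        ),
    )


class TestGeneFilter:
    def test_rate_boundary_is_strict(self):
        counts = np.zeros((100, 3), dtype=int)
        counts[:4, 0] = 1  # 4% -> dropped
        counts[:6, 1] = 1  # 6% -> kept
        counts[:5, 2] = 1  # exactly 5% -> dropped (strict >)
        cm = CountMatrix(
            sp.csr_matrix(counts),
            np.array(["A", "B", "C"], dtype=object),
            np.array([f"C{i}" for i in range(100)], dtype=object),
            np.array(["S"] * 100, dtype=object),
            np.zeros(3, dtype=bool),
        )
        assert list(gene_filter_expression_rate(cm, 0.05)) == [False, True, False]

    def test_zero_rate_keeps_any_expressed_gene(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[0, 0] = 1
        cm = CountMatrix(
            sp.csr_matrix(counts),
            np.array(["A", "B"], dtype=object),
            np.array([f"C{i}" for i in range(10)], dtype=object),
            np.array(["S"] * 10, dtype=object),
            np.zeros(2, dtype=bool),
        )
        assert list(gene_filter_expression_rate(cm, 0.0)) == [True, False]

    def test_survivor_count_matches_brute_force_on_fixture(self):
        cm, _ = fixture_small()
        flags = gene_filter_expression_rate(cm, 0.05)
        x = cm.counts.toarray()
        expected = ((x > 0).mean(axis=0) > 0.05)
        assert np.array_equal(flags, expected)


class TestMetacells:
    def test_identical_cells_give_identical_metacell_rows(self):
        nm = _nm(np.tile([1.0, 2.0, 3.0], (100, 1)))
        mcs = build_metacells(nm, ["subj"] * 100, ["arm"] * 100, target_size=50)
        assert mcs.n_metacells == 2
        assert np.allclose(mcs.expr[0], mcs.expr[1])
        assert np.allclose(mcs.expr[0], [1.0, 2.0, 3.0])

    def test_no_metacell_mixes_subtypes_or_subjects(self):
        rng = np.random.default_rng(0)
        n = 400
        nm = _nm(rng.normal(size=(n, 10)))
        subjects = rng.choice(["s1", "s2"], size=n)
        subtypes = rng.choice(["arm", "homeostatic"], size=n)
        mcs = build_metacells(nm, subjects, subtypes, target_size=30)
        for m in range(mcs.n_metacells):
            members = mcs.cell_index[mcs.assignment == m]
            assert len(set(subjects[members])) == 1
            assert len(set(subtypes[members])) == 1

    def test_expr_rows_are_member_means(self):
        rng = np.random.default_rng(1)
        nm = _nm(rng.normal(size=(120, 8)))
        mcs = build_metacells(nm, ["s"] * 120, ["t"] * 120, target_size=40)
        for m in range(mcs.n_metacells):
            members = mcs.cell_index[mcs.assignment == m]
            assert np.allclose(mcs.expr[m], nm.values[members].mean(axis=0), atol=1e-9)

    def test_library_floor_drops_small_cells(self):
        lib = np.array([100.0] * 30 + [1000.0] * 90)
        nm = _nm(np.random.default_rng(2).normal(size=(120, 5)), lib=lib)
        mcs = build_metacells(nm, ["s"] * 120, ["t"] * 120, min_library=200)
        assert mcs.cell_index.min() >= 30
        assert mcs.sizes.sum() == 90

    def test_metacell_counts_near_target_on_simulated_strata(self):
        """Stratum sizes like the microglial subtypes give ceil(n/50) +/- 30%."""
        rng = np.random.default_rng(3)
        sizes = {"homeostatic": 850, "motile": 2300, "arm": 2150, "dystrophic": 1000}
        values = rng.normal(size=(sum(sizes.values()), 12))
        subtypes = np.concatenate([[k] * v for k, v in sizes.items()])
        nm = _nm(values)
        mcs = build_metacells(nm, ["s"] * len(subtypes), subtypes, target_size=50)
        for k, n in sizes.items():
            got = np.sum(mcs.subtype_of_metacell == k)
            want = math.ceil(n / 50)
            assert abs(got - want) <= max(1, 0.3 * want), (k, got, want)

    def test_tiny_stratum_becomes_single_metacell(self):
        nm = _nm(np.random.default_rng(4).normal(size=(10, 5)))
        mcs = build_metacells(nm, ["s"] * 10, ["t"] * 10, target_size=50)
        assert mcs.n_metacells == 1
        assert mcs.sizes[0] == 10


class TestCsn:
    def test_silent_gene_has_no_edges(self):
        rng = np.random.default_rng(0)
        expr = rng.uniform(0.5, 1.5, size=(60, 5))
        expr[7, 2] = 0.0
        net = csn_one(expr, 7)
        assert net.adjacency[2].sum() == 0
        assert net.adjacency[:, 2].sum() == 0

    def test_adjacency_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        expr = rng.lognormal(size=(80, 10))
        for net in csn_all(expr)[:5]:
            assert np.array_equal(net.adjacency, net.adjacency.T)
            assert np.all(np.diag(net.adjacency) == 0)
            assert set(np.unique(net.adjacency)) <= {0, 1}

    def test_perfect_dependence_always_edges(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 1.0, size=200)
        expr = np.column_stack([x, x, rng.uniform(0.1, 1.0, size=200)])
        for q in range(0, 200, 10):
            assert csn_one(expr, q).adjacency[0, 1] == 1

    def test_null_edge_rate_controlled(self):
        """Independent uniform gene pairs: edge frequency <= alpha + 2 MC SE."""
        rng = np.random.default_rng(3)
        hits, total = 0, 0
        for _ in range(60):
            expr = rng.uniform(size=(500, 10))  # 5 independent pairs
            q = int(rng.integers(500))
            adj = csn_one(expr, q).adjacency
            for j in range(5):
                hits += int(adj[2 * j, 2 * j + 1])
                total += 1
        assert hits / total <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)

    def test_planted_module_enriched_in_average_network(self):
        rng = np.random.default_rng(4)
        n_mc, n_genes = 400, 30
        expr = rng.lognormal(0, 0.2, size=(n_mc, n_genes))
        latent = rng.lognormal(0, 1.0, size=n_mc)
        expr[:, :10] *= latent[:, None]
        avg = average_adjacency(csn_all(expr))
        iu = np.triu_indices(n_genes, k=1)
        module = (iu[0] < 10) & (iu[1] < 10)
        ratio = avg[iu][module].mean() / avg[iu][~module].mean()
        assert ratio >= 3.0

    def test_average_adjacency_is_mean_of_networks(self):
        rng = np.random.default_rng(5)
        expr = rng.lognormal(size=(40, 6))
        csns = csn_all(expr)
        manual = sum(c.adjacency.astype(float) for c in csns) / len(csns)
        assert np.allclose(average_adjacency(csns), manual)

    def test_permuting_pool_order_permutes_networks(self):
        rng = np.random.default_rng(6)
        expr = rng.lognormal(size=(30, 5))
        perm = rng.permutation(30)
        nets = csn_all(expr)
        nets_p = csn_all(expr[perm])
        for new_q, old_q in enumerate(perm):
            assert np.array_equal(nets_p[new_q].adjacency, nets[old_q].adjacency)

    def test_vectorize_shape_and_binary(self):
        rng = np.random.default_rng(7)
        expr = rng.lognormal(size=(25, 8))
        vec = vectorize_csns(csn_all(expr))
        assert vec.shape == (25, 8 * 7 // 2)
        assert set(np.unique(vec)) <= {0.0, 1.0}
        sub = vectorize_csns(csn_all(expr), gene_subset=np.arange(4))
        assert sub.shape == (25, 6)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            csn_one(np.ones((5, 3)), 0)

    def test_invalid_params_rejected(self):
        expr = np.random.default_rng(8).uniform(size=(30, 3))
        with pytest.raises(ValueError):
            csn_one(expr, 0, alpha_edge=0.0)
        with pytest.raises(ValueError):
            csn_one(expr, 0, h=-1.0)
        with pytest.raises(IndexError):
            csn_one(expr, 99)

    def test_constant_gene_gives_no_spurious_edges(self):
        rng = np.random.default_rng(9)
        expr = rng.uniform(0.5, 1.5, size=(50, 3))
        expr[:, 1] = 0.7  # constant: window covers everyone -> z = 0
        net = csn_one(expr, 3)
        assert net.adjacency[1].sum() == 0
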