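"""Wilcoxon DE, ANOVA gene selection and risk-gene z-scores."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from armnet.de import (
    de_wilcoxon,
    log2_fold_change,
    rank_sum_z,
    risk_gene_zscores,
    select_genes_anova,
)
from armnet.qc import NormalizedMatrix


def _nm(values, gene_ids=None, log=True):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=values,
        gene_ids=np.array(
            gene_ids if gene_ids is not None else [f"G{i}" for i in range(n_genes)],
            dtype=object,
        ),
        cell_ids=np.array([f"C{i}" for i in range(n_cells)], dtype=object),
        sample_of_cell=np.array(["S1"] * n_cells, dtype=object),
        log_transformed=log,
    )


class TestRankSum:
    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2, size=(25, 6)).astype(float)
        y = rng.poisson(3, size=(35, 6)).astype(float)
        _, p = rank_sum_z(x, y)
        for g in range(6):
            ref = sps.mannwhitneyu(
                x[:, g], y[:, g], alternative="two-sided", method="asymptotic"
            )
            assert p[g] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_statistic_matches_exact_enumeration_4v4(self):
        """(1,2,3,4) vs (5,6,7,8): U equals its value under full enumeration
        of all C(8,4)=70 assignments (complete separation -> U1 = 0)."""
        vals = np.arange(1, 9, dtype=float)
        ranks = sps.rankdata(vals)
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        u_all = [
            sum(ranks[list(comb)]) - 4 * 5 / 2
            for comb in itertools.combinations(range(8), 4)
        ]
        assert u_obs == 0.0
        # exact two-sided p from enumeration: equally extreme in either tail
        p_exact = np.mean([min(u, 16 - u) <= min(u_obs, 16 - u_obs) for u in u_all])
        assert p_exact == pytest.approx(2 / 70)
        z, _ = rank_sum_z(vals[:4, None], vals[4:, None])
        assert z[0] < 0  # group 1 is lower

    def test_identical_groups_not_significant(self):
        x = np.tile([1.0, 2.0], (10, 3))
        res = de_wilcoxon(_nm(np.vstack([x, x])), ["a"] * 10 + ["b"] * 10)
        assert np.all(res["p"] == 1.0)
        assert np.all(res["log2fc"] == 0.0)
        assert not res["significant"].any()


class TestDeWilcoxon:
    @pytest.fixture(scope="class")
    def planted(self):
        """200 ARM vs 200 homeostatic cells; gene 0 is a 2-fold ARM marker."""
        rng = np.random.default_rng(1)
        n = 200
        base = rng.poisson(5, size=(2 * n, 30)).astype(float)
        base[:n, 0] *= 2  # planted marker
        values = np.log1p(base / base.sum(1, keepdims=True) * 1e4)
        groups = np.array(["arm"] * n + ["homeostatic"] * n)
        return _nm(values), groups

    def test_planted_marker_recovered_up(self, planted):
        nm, groups = planted
        res = de_wilcoxon(nm, groups, mode="one_vs_homeostatic")
        row = res[(res["gene"] == "G0") & (res["group"] == "arm")].iloc[0]
        assert row["significant"]
        assert row["direction"] == "up"
        assert row["log2fc"] > 0.5

    def test_two_group_modes_coincide(self, planted):
        """one_vs_rest equals one_vs_homeostatic when the rest IS homeostatic."""
        nm, groups = planted
        a = de_wilcoxon(nm, groups, mode="one_vs_homeostatic")
        b = de_wilcoxon(nm, groups, mode="one_vs_rest")
        b_arm = b[b["group"] == "arm"].reset_index(drop=True)
        a_arm = a[a["group"] == "arm"].reset_index(drop=True)
        assert np.allclose(a_arm["p"], b_arm["p"])
        assert np.allclose(a_arm["log2fc"], b_arm["log2fc"])

    def test_bh_monotone_in_raw_p(self, planted):
        nm, groups = planted
        res = de_wilcoxon(nm, groups, mode="one_vs_rest")
        sub = res[res["group"] == "arm"].sort_values("p")
        assert sub["p_adj"].is_monotonic_increasing
        assert (sub["p_adj"] >= sub["p"]).all()

    def test_small_group_skipped(self):
        nm = _nm(np.random.default_rng(2).poisson(3, size=(12, 4)).astype(float))
        res = de_wilcoxon(nm, ["a"] * 2 + ["b"] * 10)
        assert "a" not in set(res["group"])

    def test_global_null_family_error_controlled(self):
        """Under a global null the chance of any BH-significant gene stays
        near the nominal 5% level (500 replicates, 1000 genes)."""
        rng = np.random.default_rng(3)
        n_rep, n_genes, n = 500, 1000, 20
        hits = 0
        for _ in range(n_rep):
            x = rng.normal(size=(n, n_genes))
            groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
            nm = _nm(x, log=False)
            res = de_wilcoxon(nm, groups, mode="one_vs_rest", log2fc_threshold=0.0)
            sub = res[res["group"] == "a"]
            hits += int((sub["p_adj"] < 0.05).any())
        mc_err = np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= 0.05 + 2 * mc_err


class TestAnova:
    def test_strong_between_group_gene_ranked_first(self):
        rng = np.random.default_rng(4)
        n_per, n_genes = 10, 6
        labels = np.repeat(["a", "b", "c", "d"], n_per)
        expr = rng.normal(0, 0.1, size=(4 * n_per, n_genes))
        expr[labels == "d", 0] += 5.0  # means (0,0,0,5), within-SD 0.1
        top = select_genes_anova(expr, labels, 1)
        assert list(top) == [0]

    def test_constant_gene_never_beats_varying_gene(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["a", "b"], 10)
        expr = np.column_stack(
            [np.full(20, 3.0), rng.normal(size=20) + (labels == "b")]
        )
        order = select_genes_anova(expr, labels, 2)
        assert list(order) == [1, 0]

    def test_n_select_capped_at_gene_count(self):
        rng = np.random.default_rng(6)
        expr = rng.normal(size=(12, 3))
        out = select_genes_anova(expr, ["a"] * 6 + ["b"] * 6, 10)
        assert len(out) == 3

    def test_needs_two_groups_with_two_obs(self):
        with pytest.raises(ValueError):
            select_genes_anova(np.zeros((4, 2)), ["a"] * 4, 1)
        with pytest.raises(ValueError):
            select_genes_anova(np.zeros((3, 2)), ["a", "a", "b"], 1)


class TestRiskZscores:
    def _nm_groups(self, rows, genes):
        return _nm(rows, gene_ids=genes, log=True)

    def test_twenty_percent_rule(self):
        """19% expression in every group -> dropped; 20% in one -> kept."""
        n = 100
        vals = np.zeros((2 * n, 2))
        vals[:19, 0] = 1.0
        vals[n : n + 19, 0] = 1.0  # gene A: 19% in both groups
        vals[:20, 1] = 1.0  # gene B: 20% in group a only
        nm = self._nm_groups(vals, ["A", "B"])
        groups = ["a"] * n + ["b"] * n
        z = risk_gene_zscores(nm, groups, risk_genes=("A", "B"))
        assert list(z.index) == ["B"]

    def test_two_groups_give_symmetric_z(self):
        rng = np.random.default_rng(7)
        vals = rng.poisson(2, size=(40, 1)).astype(float)
        nm = self._nm_groups(vals, ["BIN1"])
        z = risk_gene_zscores(nm, ["a"] * 20 + ["b"] * 20, risk_genes=("BIN1",))
        row = z.loc["BIN1"]
        assert row.sum() == pytest.approx(0.0, abs=1e-12)
        assert abs(row["a"]) == pytest.approx(abs(row["b"]))

    def test_constant_gene_gives_zero_row(self):
        vals = np.ones((30, 1))
        nm = self._nm_groups(vals, ["CLU"])
        z = risk_gene_zscores(nm, ["a"] * 15 + ["b"] * 15, risk_genes=("CLU",))
        assert np.all(z.loc["CLU"] == 0.0)

    def test_no_survivor_returns_empty(self):
        vals = np.zeros((30, 1))
        nm = self._nm_groups(vals, ["CR1"])
        z = risk_gene_zscores(nm, ["a"] * 15 + ["b"] * 15, risk_genes=("CR1",))
        assert z.empty


def test_log2fc_sign_convention():
    x = np.log1p(np.full((10, 1), 8.0))
    y = np.log1p(np.full((10, 1), 2.0))
    assert log2_fold_change(x, y)[0] == pytest.approx(2.0, abs=1e-6)
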