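"""Cohort filters, fold changes, linking, and correlation analyses."""

import numpy as np
import pandas as pd
import pytest

from mstarr import invivo as V
from mstarr.datamodel import GenomicWindow


class TestCpgCoverageFilter:
    def _cov(self, rows):
        return pd.DataFrame(rows)

    def test_half_of_baseline_samples_suffices(self):
        base = self._cov({"c1": [4, 4, 0, 0], "c2": [3, 3, 3, 3]})
        inf = self._cov({"c1": [0, 0, 0, 0], "c2": [0, 0, 0, 0]})
        mask = V.filter_cpg_coverage(base, inf)
        assert mask.tolist() == [True, False]

    def test_coverage_three_everywhere_dropped(self):
        base = self._cov({"c1": [3, 3, 3, 3]})
        assert not V.filter_cpg_coverage(base, base).any()

    def test_infected_only_retained(self):
        base = self._cov({"c1": [0, 0]})
        inf = self._cov({"c1": [9, 9]})
        assert V.filter_cpg_coverage(base, inf).all()


class TestGeneExpressionFilter:
    def test_cohort_mean_rule_or_across_conditions(self):
        base = pd.DataFrame({"g1": [0.5, 0.5], "g2": [0.1, 0.2]})
        inf = pd.DataFrame({"g1": [2.0, 2.2], "g2": [1.0, 1.0]})
        mask = V.filter_genes_expression(
            {"baseline": base, "infected": inf}, rule="mean-threshold"
        )
        assert mask.tolist() == [True, False]

    def test_per_sample_rule_boundary(self):
        # 2 of 6 samples above threshold: dropped; 3 of 6: kept
        m = pd.DataFrame({
            "g1": [4, 4, 0, 0, 0, 0],
            "g2": [4, 4, 4, 0, 0, 0],
        })
        mask = V.filter_genes_expression({"c": m}, rule="per-sample-threshold")
        assert mask.tolist() == [False, True]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            V.filter_genes_expression({}, rule="nope")


class TestResidualize:
    def test_orthogonal_covariate_is_noop(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        data = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]])  # constant: orthogonal to x
        out = V.residualize_covariates(data, x[:, None])
        np.testing.assert_allclose(out.values, data.values, atol=1e-12)

    def test_exact_multiple_leaves_mean(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        data = pd.DataFrame([2 * x])
        out = V.residualize_covariates(data, x[:, None])
        np.testing.assert_allclose(out.values[0], np.full(4, (2 * x).mean()), atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(20, 15)))
        cov = rng.normal(size=(15, 2))
        out = V.residualize_covariates(data, cov, restore_means=False)
        assert np.abs(out.values @ cov).max() < 1e-8

    def test_rank_deficient_rejected(self):
        x = np.ones((4, 1))  # collinear with intercept
        with pytest.raises(ValueError):
            V.residualize_covariates(pd.DataFrame([[1.0, 2, 3, 4]]), x)


class TestFoldChange:
    def test_identical_matrices_zero(self):
        m = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        assert (V.fold_change_matrix(m, m) == 0).all().all()

    def test_unit_shift(self):
        m = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
        assert (V.fold_change_matrix(m + 1, m) == 1).all().all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"))
        b = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"))
        pd.testing.assert_frame_equal(
            V.fold_change_matrix(a, b), -V.fold_change_matrix(b, a)
        )

    def test_unmatched_individual_dropped(self, caplog):
        import logging

        a = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        b = pd.DataFrame(np.ones((2, 2)), index=list("ab"))
        with caplog.at_level(logging.WARNING, logger="mstarr"):
            fc = V.fold_change_matrix(a, b)
        assert list(fc.index) == ["a", "b"]


class TestWindowMeanMethylation:
    def _win(self):
        return [GenomicWindow("chr1", 0, 600), GenomicWindow("chr1", 600, 1200)]

    def test_simple_mean(self):
        meth = pd.DataFrame([[0.2, 0.4]], index=["i1"])
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 20]})
        out = V.window_mean_methylation(meth, pos, self._win())
        assert out.loc["i1", "chr1:0-600"] == pytest.approx(0.3)

    def test_low_variance_cpgs_drop_window(self):
        rng = np.random.default_rng(2)
        meth = pd.DataFrame(0.5 + rng.normal(0, 0.05, size=(10, 2)) * 0.1)
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 700]})
        out = V.window_mean_methylation(meth, pos, self._win(), min_var=0.01)
        assert out.shape[1] == 0

    def test_single_cpg_window(self):
        meth = pd.DataFrame([[0.7]], index=["i1"])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [650]})
        out = V.window_mean_methylation(meth, pos, self._win())
        assert out.loc["i1", "chr1:600-1200"] == 0.7

    def test_output_bounded(self):
        rng = np.random.default_rng(3)
        meth = pd.DataFrame(rng.uniform(size=(8, 30)))
        pos = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 1200, 30)})
        out = V.window_mean_methylation(meth, pos, self._win())
        assert ((out >= 0) & (out <= 1)).all().all()


class TestLinking:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def test_overlapping_gene_distance_zero(self):
        wins = [GenomicWindow("chr1", 1200, 1800)]
        genes = self._genes([("g1", "chr1", 1500, 3000)])
        links = V.link_enhancers_to_genes(wins, genes)
        assert links.iloc[0]["distance"] == 0

    def test_beyond_max_distance_unlinked(self):
        wins = [GenomicWindow("chr1", 0, 600)]
        genes = self._genes([("g1", "chr1", 199_000, 200_000)])
        links = V.link_enhancers_to_genes(wins, genes, max_dist=100_000)
        assert len(links) == 0

    def test_equidistant_genes_both_linked(self):
        wins = [GenomicWindow("chr1", 10_000, 10_600)]
        genes = self._genes([
            ("left", "chr1", 8_000, 9_000),
            ("right", "chr1", 11_600, 12_600),
        ])
        links = V.link_enhancers_to_genes(wins, genes)
        assert sorted(links["gene_id"]) == ["left", "right"]

    def test_supplied_table_passthrough(self):
        table = pd.DataFrame({"window_id": ["w"], "gene_id": ["g"], "distance": [5]})
        out = V.link_enhancers_to_genes([], pd.DataFrame(), link_table=table)
        assert out["source"].iloc[0] == "table"


class TestWithinIndividualCorrelation:
    def _simple(self, y_vals):
        meth = pd.DataFrame(
            [[0.1, 0.5, 0.9]], index=["i1"],
            columns=["w1", "w2", "w3"],
        )
        resp = pd.DataFrame([y_vals], index=["i1"], columns=["g1", "g2", "g3"])
        links = pd.DataFrame({
            "window_id": ["w1", "w2", "w3"], "gene_id": ["g1", "g2", "g3"],
        })
        return meth, resp, links

    def test_perfect_negative(self):
        meth, resp, links = self._simple([-0.1, -0.5, -0.9])
        out = V.within_individual_correlation(meth, resp, links)
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # x=(1,2,3) scaled into [0,1]; y=(1,2,4): r = 1.5/(1*1.52753) = 0.98198
        meth, resp, links = self._simple([1.0, 2.0, 4.0])
        meth.iloc[0] = [0.1, 0.2, 0.3]
        out = V.within_individual_correlation(meth, resp, links)
        assert out["r"].iloc[0] == pytest.approx(0.981981, abs=1e-5)

    def test_too_few_pairs_skipped(self, caplog):
        import logging

        meth = pd.DataFrame([[0.5, 0.6]], index=["i1"], columns=["w1", "w2"])
        resp = pd.DataFrame([[1.0, 2.0]], index=["i1"], columns=["g1", "g2"])
        links = pd.DataFrame({"window_id": ["w1", "w2"], "gene_id": ["g1", "g2"]})
        with caplog.at_level(logging.WARNING, logger="mstarr"):
            out = V.within_individual_correlation(meth, resp, links)
        assert len(out) == 0

    def test_multi_gene_window_uses_mean_response(self):
        meth = pd.DataFrame([[0.2, 0.4, 0.8]], index=["i1"],
                            columns=["w1", "w2", "w3"])
        resp = pd.DataFrame([[1.0, 3.0, 2.0, 4.0]], index=["i1"],
                            columns=["g1", "g1b", "g2", "g3"])
        links = pd.DataFrame({
            "window_id": ["w1", "w1", "w2", "w3"],
            "gene_id": ["g1", "g1b", "g2", "g3"],
        })
        out = V.within_individual_correlation(meth, resp, links)
        # w1 response = mean(1,3) = 2 -> responses (2,2,4) vs (0.2,0.4,0.8)
        expected = np.corrcoef([0.2, 0.4, 0.8], [2.0, 2.0, 4.0])[0, 1]
        assert out["r"].iloc[0] == pytest.approx(expected)


class TestLocuswise:
    def test_planted_signal_top_ranked(self):
        rng = np.random.default_rng(4)
        n_ind, n_pairs = 30, 50
        meth = pd.DataFrame(rng.uniform(0.2, 0.8, size=(n_ind, n_pairs)),
                            columns=[f"w{i}" for i in range(n_pairs)])
        fc = pd.DataFrame(rng.normal(size=(n_ind, n_pairs)),
                          columns=[f"g{i}" for i in range(n_pairs)])
        fc["g0"] = -3.0 * meth["w0"] + rng.normal(0, 0.05, n_ind)
        links = pd.DataFrame({"window_id": [f"w{i}" for i in range(n_pairs)],
                              "gene_id": [f"g{i}" for i in range(n_pairs)]})
        out = V.locuswise_association(meth, fc, links)
        assert out.iloc[0]["window_id"] == "w0"
        assert out.iloc[0]["r2"] > 0.9

    def test_too_few_individuals_rejected(self):
        meth = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            V.locuswise_association(meth, meth, pd.DataFrame())


class TestGroupTtest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = V.group_response_ttest(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_degenerate_paired_flagged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mstarr"):
            t, df, p = V.group_response_ttest(
                np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0]), paired=True
            )
        assert np.isinf(t) and p == 0.0

    def test_welch_satterthwaite_df(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0, 3, size=7)
        t, df, p = V.group_response_ttest(a, b)
        va, vb = a.var(ddof=1) / 12, b.var(ddof=1) / 7
        df_oracle = (va + vb) ** 2 / (va**2 / 11 + vb**2 / 6)
        assert df == pytest.approx(df_oracle, rel=1e-10)

    def test_fisher_z_ci_coverage(self):
        # CIs cover the true r in ~95% of simulations at n = 35
        rng = np.random.default_rng(6)
        true_r = -0.4
        cover = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.normal(size=35)
            y = true_r * x + np.sqrt(1 - true_r**2) * rng.normal(size=35)
            r = np.corrcoef(x, y)[0, 1]
            lo, hi = V._fisher_z_ci(r, 35)
            cover += lo <= true_r <= hi
        assert abs(cover / n_rep - 0.95) < 0.03
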