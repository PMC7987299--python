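"""Conditional/joint algebra: oracles against individual-level regressions."""

import numpy as np
import pandas as pd
import pytest

from twaskit import (conditional_arithmetic, conditional_region_summary,
                     conditional_snp_z, feature_correlation,
                     feature_correlation_matrix, group_regions,
                     joint_gene_analysis, load_table2_fixture, zscore_to_p)
from twaskit.cojo import Region
from twaskit.weights import WeightModel

from conftest import make_gwas, make_ld
from test_association import wm_from


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestRegions:
    def test_within_window_merged(self):
        g = genes_frame([("a", "1", 1_000_000, 1_000_000),
                         ("b", "1", 1_400_000, 1_400_000)])
        regions = group_regions(g, window=500_000)
        assert len(regions) == 1
        assert regions[0].gene_ids == ["a", "b"]

    def test_transitive_chaining(self):
        g = genes_frame([("a", "1", 1_000_000, 1_000_000),
                         ("b", "1", 1_400_000, 1_400_000),
                         ("c", "1", 1_900_000, 1_900_000)])
        regions = group_regions(g, window=500_000)
        # oracle: explicit transitive closure on the 3-gene instance
        d_ab, d_bc, d_ac = 400_000, 500_000, 900_000
        linked = {("a", "b"): d_ab <= 500_000, ("b", "c"): d_bc <= 500_000,
                  ("a", "c"): d_ac <= 500_000}
        assert linked[("a", "b")] and linked[("b", "c")] and not linked[("a", "c")]
        assert len(regions) == 1          # a-b and b-c chain all three
        assert regions[0].gene_ids == ["a", "b", "c"]

    def test_chromosomes_never_merge(self):
        g = genes_frame([("a", "1", 1_000_000, 1_000_000),
                         ("b", "2", 1_000_000, 1_000_000)])
        assert len(group_regions(g, window=500_000)) == 2


class TestFeatureCorrelation:
    def test_identical_weights(self):
        S = np.eye(3)
        w = np.array([1.0, 0.5, 0.0])
        assert feature_correlation(w, w, make_ld(list("abc"), S)) == pytest.approx(1.0)

    def test_disjoint_identity(self):
        S = np.eye(4)
        wj = np.array([1.0, 1.0, 0.0, 0.0])
        wk = np.array([0.0, 0.0, 1.0, -1.0])
        assert feature_correlation(wj, wk, make_ld(list("abcd"), S)) == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            feature_correlation(np.zeros(2), np.ones(2), make_ld(["a", "b"], np.eye(2)))

    def test_matches_individual_level_oracle(self):
        """Formula equals the correlation of predicted expression computed
        from simulated genotypes on a 5-SNP toy locus."""
        rng = np.random.default_rng(5)
        n, m = 4000, 5
        L = np.linalg.cholesky(0.5 * np.eye(m) + 0.5 * np.ones((m, m)))
        X = rng.standard_normal((n, m)) @ L.T
        X = (X - X.mean(0)) / X.std(0)
        S = np.corrcoef(X, rowvar=False)
        wj = rng.normal(size=m)
        wk = rng.normal(size=m)
        r_formula = feature_correlation(wj, wk, make_ld(list("abcde"), S))
        r_direct = np.corrcoef(X @ wj, X @ wk)[0, 1]
        assert r_formula == pytest.approx(r_direct, abs=0.02)


class TestJointAnalysis:
    def test_identity_R_joint_equals_marginal(self):
        z = np.array([3.0, -2.0])
        jr = joint_gene_analysis(z, np.eye(2))
        assert np.allclose(jr.joint_z, z)
        assert np.allclose(jr.joint_p, jr.marginal_p)

    def test_single_gene_joint_equals_marginal(self):
        jr = joint_gene_analysis(np.array([4.2]), np.eye(1))
        assert jr.joint_z[0] == pytest.approx(4.2)

    def test_perfectly_collinear_pruned(self):
        z = np.array([5.0, 4.0])
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        jr = joint_gene_analysis(z, R)
        assert jr.pruned == ["gene1"]         # smaller |z| pruned
        assert np.isnan(jr.joint_z[1])
        assert jr.joint_z[0] == pytest.approx(5.0)

    def test_matches_normal_equations_oracle(self):
        """Marginal z from the published 2q33 pair; independent solve."""
        z = np.array([6.7, -5.22])
        r = -0.35
        R = np.array([[1.0, r], [r, 1.0]])
        jr = joint_gene_analysis(z, R)
        # independently coded: explicit 2x2 inversion
        det = 1 - r * r
        Ri = np.array([[1.0, -r], [-r, 1.0]]) / det
        b = Ri @ z
        expected = b / np.sqrt(np.diag(Ri))
        assert np.allclose(jr.joint_z, expected, atol=1e-8)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 3, 4)
        A = rng.standard_normal((4, 6))
        R = np.corrcoef(A)
        jr = joint_gene_analysis(z, R, gene_ids=list("abcd"))
        perm = [2, 0, 3, 1]
        jr2 = joint_gene_analysis(z[perm], R[np.ix_(perm, perm)],
                                  gene_ids=[list("abcd")[i] for i in perm])
        for i, g in enumerate(jr.gene_ids):
            j = jr2.gene_ids.index(g)
            assert jr2.joint_z[j] == pytest.approx(jr.joint_z[i], abs=1e-10)


class TestConditionalSnpZ:
    def test_uncorrelated_gene_changes_nothing(self):
        z, flag = conditional_snp_z(2.5, np.zeros(2), np.eye(2), np.array([4.0, 3.0]))
        assert not flag and z == pytest.approx(2.5)

    def test_self_conditioning_fully_explained(self):
        z, flag = conditional_snp_z(3.0, np.array([1.0]), np.eye(1), np.array([3.0]))
        assert flag

    def test_matches_individual_level_regression_oracle(self):
        """3-SNP toy locus: summary conditional z vs two-stage OLS."""
        rng = np.random.default_rng(11)
        n, m = 6000, 3
        L = np.linalg.cholesky(np.array([[1.0, 0.5, 0.25],
                                         [0.5, 1.0, 0.5],
                                         [0.25, 0.5, 1.0]]))
        X = rng.standard_normal((n, m)) @ L.T
        X = (X - X.mean(0)) / X.std(0)
        S = np.corrcoef(X, rowvar=False)
        w = np.array([0.6, 0.3, 0.0])
        feat = X @ w
        feat_s = (feat - feat.mean()) / feat.std()
        y = 0.05 * feat_s + rng.standard_normal(n)

        def ols_z(design, target, col):
            design = np.column_stack([np.ones(len(target)), design])
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            resid = target - design @ coef
            dof = len(target) - design.shape[1]
            sigma2 = resid @ resid / dof
            cov = sigma2 * np.linalg.inv(design.T @ design)
            return coef[col + 1] / np.sqrt(cov[col + 1, col + 1])

        for s in range(m):
            z_marg = ols_z(X[:, [s]], y, 0)
            z_gene = ols_z(feat_s[:, None], y, 0)
            z_cond_oracle = ols_z(np.column_stack([X[:, s], feat_s]), y, 0)
            rho_s = (S @ w)[s] / np.sqrt(w @ S @ w)
            z_cond, flag = conditional_snp_z(
                z_marg, np.array([rho_s]), np.eye(1), np.array([z_gene]))
            assert not flag
            assert z_cond == pytest.approx(z_cond_oracle, abs=0.05)


class TestConditionalSummary:
    def test_arithmetic_stated_rows(self):
        r, m, _ = conditional_arithmetic(12, 1, 8.2e-17, 6.4e-9)
        assert round(r, 2) == 0.92 and m == pytest.approx(1.28e-8, rel=0.01)
        r, m, _ = conditional_arithmetic(12, 6, 8.2e-17, 3.9e-12)
        assert round(r, 2) == 0.50 and m == pytest.approx(2.10e-5, rel=0.01)

    def test_unchanged_index_p_magnitude_one(self):
        r, m, _ = conditional_arithmetic(36, 36, 2.8e-44, 2.8e-44)
        assert m == pytest.approx(1.0)
        assert r == pytest.approx(0.0)

    def test_nothing_significant_convention(self):
        r, m, flag = conditional_arithmetic(0, 0, 1e-3, 1e-2)
        assert r == 1.0 and flag

    def test_fixture_rows_all_consistent(self):
        t2 = load_table2_fixture()
        for row in t2.itertuples(index=False):
            r, m, _ = conditional_arithmetic(row.n_sig_before, row.n_sig_after,
                                             row.index_p, row.min_conditional_p)
            assert round(r, 2) == pytest.approx(row.ratio, abs=0.005)
            assert m == pytest.approx(row.magnitude, rel=0.01)

    def test_mediated_locus_conditioning_removes_signal(self):
        """Conditioning on the causal gene on a fully mediated locus drives
        genome-wide-significant SNPs to (near) zero."""
        from twaskit import (SimulationConfig, fit_weights, ld_matrix,
                            regularize_ld, simulate_expression,
                            simulate_genotype_panel)
        from twaskit.simulate import simulate_subtype_gwas

        cfg0 = SimulationConfig(
            n_ref_individuals=500, n_snps=30, n_causal_eqtl=3, h2_cis=0.6,
            ld_rho=0.5, alpha_pos=0.04, alpha_neg=0.04, seed=23)
        panel = simulate_genotype_panel(cfg0)
        expr, truth = simulate_expression(panel, cfg0)
        ids = list(panel.snps["snp_id"])
        wm = fit_weights(panel.dosages, expr, None, "enet", gene_id="g1",
                         snp_ids=ids)
        ld = regularize_ld(ld_matrix(panel, ids), 0.1)
        region = Region(chrom="1", start=0, end=10**9, gene_ids=["g1"])
        cleared = 0
        reps = 40
        for seed in range(reps):
            cfg = SimulationConfig(**{**cfg0.__dict__, "seed": seed})
            scan = simulate_subtype_gwas(panel, truth, cfg)["overall"]
            summary, _ = conditional_region_summary(region, scan, [wm], panel, ld)
            if summary.n_sig_before > 0 and summary.n_sig_after <= 1:
                cleared += 1
            elif summary.n_sig_before == 0:
                reps -= 1
        assert cleared / max(reps, 1) >= 0.8

    def test_uncorrelated_gene_leaves_track_unchanged(self):
        """Conditioning on a gene uncorrelated with the region's SNPs."""
        ids = ["s0", "s1", "s2", "g_snp"]
        S = np.eye(4)
        ld = make_ld(ids, S)
        wm = WeightModel(gene_id="g", method="top1", snp_ids=["g_snp"],
                         a1=["A"], a2=["G"], weights=np.array([1.0]))
        gwas = make_gwas(ids, [2.0, -1.0, 6.0, 0.5])
        region = Region(chrom="1", start=0, end=10**9, gene_ids=["g"])
        _, track = conditional_region_summary(region, gwas, [wm], None, ld)
        sub = track[track["snp"] != "g_snp"]
        assert np.allclose(sub["z_marginal"], sub["z_conditional"], atol=1e-10)
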