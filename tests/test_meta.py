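"""Sample-size-weighted meta-analysis, BH FDR, and novelty annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import grexpipe as gp
from grexpipe.errors import InvalidInputError

# Published per-study (z, N) pairs and combined z for five novel
# late-onset-Alzheimer's genes (first cohort consortium + summary cohort).
TABLE1 = {
    "TRIT1": ([(3.025, 25776), (3.487, 32937)], 4.615),
    "TSPAN14": ([(2.224, 25687), (4.136, 32937)], 4.572),
    "LRRC8D": ([(-3.599, 25776), (-2.815, 32937)], -4.493),
    "CLUAP1": ([(3.948, 24133), (2.310, 32007)], 4.333),
    "RERE": ([(-1.440, 25776), (-4.399, 32937)], -4.249),
}


def brute_force_bh(p):
    """Step-up definition applied literally: adj_(i) = min over j >= i of
    min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


class TestCombineZ:
    def test_single_study_identity(self):
        res = gp.combine_z([(1.7, 500)])
        assert res.z == pytest.approx(1.7, rel=1e-12)
        assert res.n_studies == 1

    def test_equal_n_opposite_z_cancel(self):
        res = gp.combine_z([(2.0, 1000), (-2.0, 1000)])
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("gene", sorted(TABLE1))
    def test_published_combined_z_reproduced(self, gene):
        """sqrt(N)-weighted combination reproduces the published combined
        z-scores from the printed per-study rows (inputs rounded to 3 dp)."""
        pairs, expected = TABLE1[gene]
        res = gp.combine_z(pairs)
        assert res.z == pytest.approx(expected, abs=0.005)

    def test_study_permutation_invariance(self):
        pairs = [(1.1, 300), (-0.4, 1200), (2.2, 800)]
        a = gp.combine_z(pairs)
        b = gp.combine_z(pairs[::-1])
        assert a.z == pytest.approx(b.z, rel=1e-14)

    def test_duplicate_study_changes_result(self):
        """No double-count protection is claimed: listing a study twice
        changes the combined statistic."""
        once = gp.combine_z([(2.0, 1000), (1.0, 500)])
        twice = gp.combine_z([(2.0, 1000), (2.0, 1000), (1.0, 500)])
        assert once.z != pytest.approx(twice.z)

    def test_null_z_is_standard_normal(self):
        """Over 1e5 simulated null genes with heterogeneous study sizes the
        combined z has mean ~0 and variance ~1."""
        rng = np.random.default_rng(61)
        n_i = np.array([800.0, 1500.0, 3000.0])
        w = np.sqrt(n_i) / np.sqrt(n_i.sum())
        Z = rng.standard_normal((100_000, 3)) @ w
        # sanity-check the vectorized oracle against combine_z on a few rows
        z_raw = rng.standard_normal((5, 3))
        for row in z_raw:
            expect = float(row @ w)
            got = gp.combine_z(list(zip(row, n_i))).z
            assert got == pytest.approx(expect, rel=1e-12)
        assert abs(Z.mean()) < 0.01
        assert abs(Z.var() - 1.0) < 0.02

    def test_nonpositive_n_rejected(self):
        with pytest.raises(InvalidInputError):
            gp.combine_z([(1.0, 0)])


class TestZToP:
    def test_zero_z_gives_p_one(self):
        assert gp.z_to_p(0.0) == 1.0

    def test_standard_normal_quantile(self):
        assert gp.z_to_p(1.959964) == pytest.approx(0.05, rel=1e-5)

    def test_published_meta_pvalues(self):
        """Combined z for the top published genes converts to the printed
        meta p-values at their printed precision."""
        z_trit1 = gp.combine_z(TABLE1["TRIT1"][0]).z
        assert abs(gp.z_to_p(z_trit1) - 3.92e-6) <= 0.01e-6
        z_cluap1 = gp.combine_z(TABLE1["CLUAP1"][0]).z
        assert abs(gp.z_to_p(z_cluap1) - 1.47e-5) <= 0.01e-5


class TestBH:
    def test_all_ones_stay_ones(self):
        out = gp.bh_adjust([1.0] * 5)
        assert (out["p_adj"] == 1.0).all()
        assert not out["significant"].any()

    def test_hand_applied_step_up(self):
        out = gp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out["p_adj"], [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_on_random_pvalues(self):
        rng = np.random.default_rng(67)
        p = rng.random(10_000)
        out = gp.bh_adjust(p)
        np.testing.assert_allclose(
            out["p_adj"].to_numpy(), brute_force_bh(p), rtol=0, atol=0
        )

    def test_agrees_with_statsmodels_route(self):
        """Independent library route: statsmodels' fdr_bh agrees to float
        noise (it divides where the step-up definition multiplies)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(68)
        p = rng.random(2000)
        mine = gp.bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine["p_adj"].to_numpy(), ref, rtol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(71)
        p = rng.random(500)
        out = gp.bh_adjust(p)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        srt = out.sort_values("p")
        assert (np.diff(srt["p_adj"]) >= -1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(InvalidInputError):
            gp.bh_adjust([0.5, 0.0])

    def test_fdr_controlled_on_mixture(self):
        """Empirical FDR <= 0.05 (+MC slack) on a 10% true-effect mixture
        over 50 replicates."""
        rng = np.random.default_rng(73)
        fdps = []
        for _ in range(50):
            m = 1000
            truth = rng.random(m) < 0.10
            z = rng.standard_normal(m) + np.where(truth, 4.0, 0.0)
            p = 2 * norm.sf(np.abs(z))
            out = gp.bh_adjust(p)
            rejected = out["significant"].to_numpy()
            if rejected.sum():
                fdps.append((rejected & ~truth).sum() / rejected.sum())
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 0.06


class TestNovelty:
    def test_gene_at_known_snp_position(self):
        genes = pd.DataFrame({"gene": ["G1"], "chrom": ["1"], "pos": [5_000_000]})
        snps = pd.DataFrame({"snp": ["rsK"], "chrom": ["chr1"], "pos": [5_000_000]})
        out = gp.annotate_known_loci(genes, snps)
        assert out.iloc[0]["within_window"]
        assert out.iloc[0]["distance"] == 0

    def test_boundary_is_strictly_outside(self):
        genes = pd.DataFrame(
            {"gene": ["G1", "G2"], "chrom": ["1", "1"],
             "pos": [20_000_000, 20_000_001]}
        )
        snps = pd.DataFrame({"snp": ["rsK"], "chrom": ["1"], "pos": [10_000_000]})
        out = gp.annotate_known_loci(genes, snps)
        assert out.iloc[0]["within_window"]        # exactly 10 Mb away
        assert not out.iloc[1]["within_window"]    # one bp further: novel

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(79)
        genes = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(50)],
                "chrom": rng.choice(["1", "2"], 50),
                "pos": rng.integers(1, 60_000_000, 50),
            }
        )
        snps = pd.DataFrame(
            {
                "snp": ["rsA", "rsB", "rsC"],
                "chrom": ["1", "2", "chr2"],
                "pos": [12_000_000, 40_000_000, 5_000_000],
            }
        )
        out = gp.annotate_known_loci(genes, snps)
        for _, g in genes.iterrows():
            expected = False
            for _, s in snps.iterrows():
                same = str(s["chrom"]).replace("chr", "") == str(g["chrom"])
                if same and abs(int(s["pos"]) - int(g["pos"])) <= 10_000_000:
                    expected = True
            got = out.loc[out["gene"] == g["gene"], "within_window"].iloc[0]
            assert got == expected


def test_meta_analyze_pools_studies_and_flags_significance():
    assoc = pd.DataFrame(
        {
            "GENE": ["G1", "G1", "G2", "G2"],
            "TISSUE": ["t", "t", "t", "t"],
            "Z": [3.5, 3.0, 0.1, -0.2],
            "N": [1000, 2000, 1000, 2000],
        }
    )
    out = gp.meta_analyze(assoc)
    g1 = out[out["GENE"] == "G1"].iloc[0]
    expected = (np.sqrt(1000) * 3.5 + np.sqrt(2000) * 3.0) / np.sqrt(3000)
    assert g1["Z"] == pytest.approx(expected, rel=1e-12)
    assert g1["N"] == 3000 and g1["N_STUDIES"] == 2
    assert bool(g1["SIGNIFICANT"])
    assert not bool(out[out["GENE"] == "G2"]["SIGNIFICANT"].iloc[0])
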