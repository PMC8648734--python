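"""Synthetic-cohort generator: determinism, LD structure, truth recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

import grexpipe as gp
from grexpipe.errors import InvalidConfigError


def _adjacent_r2(dosage, block_size):
    """Mean squared correlation of within-block adjacent variant pairs."""
    vals = dosage.values
    r2 = []
    for j in range(vals.shape[1] - 1):
        if (j + 1) % block_size == 0:
            continue  # block boundary
        a, b = vals[:, j], vals[:, j + 1]
        if a.std() == 0 or b.std() == 0:
            continue
        r2.append(np.corrcoef(a, b)[0, 1] ** 2)
    return float(np.mean(r2))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(maf_range=(0.0, 0.3)),
            dict(maf_range=(0.2, 0.6)),
            dict(case_fraction=(0.0, 0.2, 0.5)),
            dict(ld_rho=1.0),
            dict(n_genes=100, snps_per_gene=6, n_variants=240),
            dict(n_per_study=(100, 100)),
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            gp.SimulationConfig(**kwargs)


class TestGenotypes:
    def test_same_seed_bitidentical(self):
        cfg = gp.SimulationConfig(
            n_studies=1, n_per_study=(200,), case_fraction=(0.3,), seed=7
        )
        a = gp.simulate_genotypes(cfg)
        b = gp.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.variant_meta, b.variant_meta)

    def test_independent_variants_when_rho_zero(self):
        cfg = gp.SimulationConfig(
            n_studies=1, n_per_study=(2000,), case_fraction=(0.3,),
            ld_rho=0.0, seed=5,
        )
        d = gp.simulate_genotypes(cfg)
        assert _adjacent_r2(d, cfg.block_size) < 0.01

    def test_realized_maf_within_binomial_error_of_target(self):
        """Target MAF 0.3 at n=5000: realized frequency is a mean of 2n
        Bernoulli draws, so it must sit within 3 binomial SDs."""
        n = 5000
        cfg = gp.SimulationConfig(
            n_studies=1, n_per_study=(n,), case_fraction=(0.3,),
            maf_range=(0.3, 0.3), ld_rho=0.0, n_variants=60, n_genes=10, seed=13,
        )
        d = gp.simulate_genotypes(cfg)
        freq = d.values.mean(axis=0) / 2.0
        tol = 3 * np.sqrt(0.3 * 0.7 / (2 * n))
        assert np.all(np.abs(freq - 0.3) < tol)

    def test_dosages_bounded_and_r2_in_unit_interval(self, first_cohort):
        d = first_cohort.dosages
        assert d.values.min() >= 0 and d.values.max() <= 2
        assert (d.variant_meta["r2"] > 0).all() and (d.variant_meta["r2"] <= 1).all()

    def test_ld_increases_monotonically_with_rho(self):
        r2s = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            cfg = gp.SimulationConfig(
                n_studies=1, n_per_study=(5000,), case_fraction=(0.3,),
                ld_rho=rho, seed=21,
            )
            r2s.append(_adjacent_r2(gp.simulate_genotypes(cfg), cfg.block_size))
        assert all(a < b for a, b in zip(r2s, r2s[1:])), r2s


class TestWeightModels:
    def test_full_sharing_with_fixed_tissue_factor_copies_models(self):
        """sharing=1 and tissue factor fixed at 1 make every tissue's model
        identical once weights are expressed on a common allele scale."""
        cfg = gp.SimulationConfig(
            cross_tissue_sharing=1.0, tissue_factor_sd=0.0, seed=9
        )
        vt = gp.simulate_variant_table(cfg)
        models = gp.simulate_weight_models(vt, cfg)

        def alt_scale(m):
            e = m.entries
            w = np.where(e["effect_allele"] == e["alt"], e["weight"], -e["weight"])
            return dict(zip(e["rsid"], np.round(w, 12)))

        by_gene = {}
        for m in models:
            by_gene.setdefault(m.gene, []).append(alt_scale(m))
        for gene, reprs in by_gene.items():
            assert all(r == reprs[0] for r in reprs[1:]), gene

    def test_mean_nonzero_count_matches_binomial_oracle(self):
        """Causal-tissue models hold a lead SNP plus max(1, Binomial(9, 0.5))
        secondaries; the mean count over 200 genes must sit within 3 SDs of
        that expectation."""
        cfg = gp.SimulationConfig(
            n_genes=200, snps_per_gene=10, n_variants=2000,
            weight_sparsity=0.5, seed=31,
        )
        vt = gp.simulate_variant_table(cfg)
        models = [
            m for m in gp.simulate_weight_models(vt, cfg)
            if m.tissue == cfg.causal_tissue
        ]
        counts = np.array([m.n_snps for m in models])
        # E[1 + max(1, B)] with B ~ Binomial(9, 0.5): forcing only moves mass at B=0
        expected = 1 + 4.5 + (0.5**9)
        sd_mean = np.sqrt(9 * 0.25) / np.sqrt(200)
        assert abs(counts.mean() - expected) < 3 * sd_mean

    def test_too_many_genes_for_variant_map_raises(self):
        cfg = gp.SimulationConfig(seed=1)
        vt = gp.simulate_variant_table(cfg).iloc[:10]
        with pytest.raises(InvalidConfigError):
            gp.simulate_weight_models(vt, cfg)


class TestPhenotype:
    def test_null_model_recovers_target_case_fraction(self):
        """All effects zero, target 0.3, n=10000: the realized fraction is a
        binomial mean and must lie within 3 SDs of the target."""
        n = 10_000
        cfg = gp.SimulationConfig(
            n_studies=1, n_per_study=(n,), case_fraction=(0.3,),
            covar_effects=(0.0, 0.0), seed=23,
        )
        d = gp.simulate_genotypes(cfg)
        truth = gp.make_truth(cfg, effects={})
        y, alpha, _ = gp.simulate_phenotype(d, [], truth, cfg)
        assert abs(y.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_prevalence_control_across_seeds(self):
        """Realized case fraction stays within Monte-Carlo error of the
        target across 20 seeds."""
        n, target = 2000, 0.25
        tol = 4 * np.sqrt(target * (1 - target) / n)
        for seed in range(20):
            cfg = gp.SimulationConfig(
                n_studies=1, n_per_study=(n,), case_fraction=(target,),
                n_variants=60, n_genes=10, n_causal_genes=1, seed=300 + seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cohorts, _, _ = gp.simulate_study_set(cfg)
            assert abs(cohorts[0].phenotype.mean() - target) < tol

    def test_liability_effect_recovered_by_logistic_regression(self):
        """Single causal gene with beta=0.5 at n=20000: regressing status on
        the true GReX recovers beta within its 95% CI (estimator consistency)."""
        import statsmodels.api as sm

        cfg = gp.SimulationConfig(
            n_studies=1, n_per_study=(20_000,), case_fraction=(0.3,),
            n_variants=60, n_genes=10, seed=41,
        )
        vt = gp.simulate_variant_table(cfg)
        models = gp.simulate_weight_models(vt, cfg)
        truth = gp.make_truth(cfg, effects={"G0003": 0.5})
        d = gp.simulate_genotypes(cfg)
        y, _, covs = gp.simulate_phenotype(d, models, truth, cfg)
        grex = gp.impute_grex(
            d, [m for m in models if m.tissue == cfg.causal_tissue and m.gene == "G0003"]
        )
        g = grex.values.iloc[:, 0].to_numpy()
        age = covs["AGE"].to_numpy()
        X = sm.add_constant(
            np.column_stack([g, covs["SEX"], (age - age.mean()) / age.std()])
        )
        res = sm.Logit(y, X).fit(disp=0)
        lo, hi = res.conf_int()[1]
        assert lo < 0.5 < hi

    def test_positive_effect_raises_case_grex(self):
        cfg = gp.SimulationConfig(
            n_studies=1, n_per_study=(4000,), case_fraction=(0.4,),
            n_variants=60, n_genes=10, seed=43,
        )
        vt = gp.simulate_variant_table(cfg)
        models = gp.simulate_weight_models(vt, cfg)
        truth = gp.make_truth(cfg, effects={"G0001": 2.0})
        d = gp.simulate_genotypes(cfg)
        y, _, _ = gp.simulate_phenotype(d, models, truth, cfg)
        grex = gp.impute_grex(
            d, [m for m in models if m.tissue == cfg.causal_tissue and m.gene == "G0001"]
        )
        g = grex.values.iloc[:, 0].to_numpy()
        assert g[y == 1].mean() > g[y == 0].mean()


@pytest.fixture(scope="module")
def gwas(study_set):
    cohorts, models, _ = study_set
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gp.compute_gwas_summary(cohorts[1], models), cohorts[1], models


class TestGwasSummary:
    def test_z_concordant_with_statsmodels_wald(self, gwas):
        """Per-variant z must agree (r > 0.99) with an independent textbook
        Wald computation on the same data."""
        import statsmodels.api as sm

        (stats, _), cohort, _ = gwas
        y = cohort.phenotype.astype(float)
        C = cohort.covariates.to_numpy(float)
        z_ref = []
        for j in range(min(60, cohort.dosages.n_variants)):
            X = sm.add_constant(np.column_stack([C, cohort.dosages.values[:, j]]))
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            z_ref.append(res.params[-1] / res.bse[-1])
        r = np.corrcoef(stats["Z"].to_numpy()[: len(z_ref)], z_ref)[0, 1]
        assert r > 0.99

    def test_ld_diagonal_equals_dosage_variances(self, gwas):
        (_, ld), cohort, _ = gwas
        rsid_col = {r: i for i, r in enumerate(cohort.dosages.variant_meta["rsid"])}
        for gene in ld.genes()[:5]:
            rsids, gamma = ld.gene(gene)
            for k, rs in enumerate(rsids):
                v = cohort.dosages.values[:, rsid_col[rs]].var(ddof=1)
                assert gamma[k, k] == pytest.approx(v, rel=1e-10)

    def test_null_variants_have_moderate_z(self, gwas):
        """No causal signal on most variants: |z| < 4 essentially always."""
        (stats, _), _, _ = gwas
        assert (stats["Z"].abs() < 4).mean() > 0.98

    def test_ld_matrices_symmetric_psd(self, gwas):
        (_, ld), _, _ = gwas
        for gene in ld.genes()[:10]:
            _, gamma = ld.gene(gene)
            assert np.allclose(gamma, gamma.T)
            assert np.linalg.eigvalsh(gamma).min() > -1e-8


def test_study_set_determinism(default_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, _, ta = gp.simulate_study_set(default_config)
        b, _, tb = gp.simulate_study_set(default_config)
    assert ta.causal_genes == tb.causal_genes
    for ca, cb in zip(a, b):
        np.testing.assert_array_equal(ca.dosages.values, cb.dosages.values)
        np.testing.assert_array_equal(ca.phenotype, cb.phenotype)
        pd.testing.assert_frame_equal(ca.covariates, cb.covariates)
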