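"""Synthetic multi-study cohorts with known ground truth.

The generator emulates the study design of a multi-cohort case-control
TWAS: several studies of unequal size and case:control balance genotyped on
a shared variant map, sparse cis-eQTL weight models with partial
cross-tissue sharing, a logistic liability driven by true genetically
regulated expression in one causal tissue plus sex and age, and per-study
GWAS summary statistics with a matching LD reference.

Haplotypes come from a Gaussian-copula AR(1) block model: within each block
of ``block_size`` variants a latent standard-normal AR(1) process with
correlation ``ld_rho`` is thresholded at the MAF quantile, giving tunable
linkage disequilibrium without a real reference panel.  All randomness flows
from a single integer seed through named ``numpy.random.SeedSequence``
spawn keys, so each operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .errors import InvalidConfigError, InvalidInputError
from .grex import DosageMatrix, GReXMatrix, WeightModel, impute_grex

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "TruthRecord",
    "simulate_variant_table",
    "simulate_genotypes",
    "simulate_weight_models",
    "make_truth",
    "simulate_phenotype",
    "simulate_cohort",
    "simulate_study_set",
    "compute_gwas_summary",
    "build_ld_reference",
    "logistic_gwas",
    "BRAIN_PREFIX",
]

#: tissue labels starting with this prefix count as brain tissues
BRAIN_PREFIX = "brain"

# spawn keys of the seed-splitting scheme (documented, stable)
_K_VARIANTS = 1
_K_WEIGHTS = 2
_K_TRUTH = 3
_K_HAPLO = 4  # + study index
_K_COVAR = 5  # + study index
_K_PHENO = 6  # + study index


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SimulationConfig:
    """Parameters of one multi-study synthetic experiment.

    Defaults are desk-scale study conditions: three studies with unequal N
    and case:control imbalance (echoing a consortium of heterogeneous
    cohorts), one cis block of LD per gene, and a dominant-lead sparse
    eQTL architecture.
    """

    n_studies: int = 3
    n_per_study: tuple[int, ...] = (1500, 1000, 2500)
    case_fraction: tuple[float, ...] = (0.35, 0.2, 0.5)
    n_variants: int = 240
    n_genes: int = 40
    n_tissues: int = 6
    ld_rho: float = 0.85
    block_size: int = 6
    maf_range: tuple[float, float] = (0.1, 0.5)
    snps_per_gene: int = 6
    weight_sparsity: float = 0.4
    cross_tissue_sharing: float = 0.7
    tissue_factor_sd: float = 0.2
    n_causal_genes: int = 4
    effect_sd: float = 0.25
    covar_effects: tuple[float, float] = (0.25, 0.4)
    n_genetic_pcs: int = 4
    seed: int = 17

    def __post_init__(self) -> None:
        counts = dict(
            n_studies=self.n_studies,
            n_variants=self.n_variants,
            n_genes=self.n_genes,
            n_tissues=self.n_tissues,
            block_size=self.block_size,
            snps_per_gene=self.snps_per_gene,
        )
        for name, v in counts.items():
            if int(v) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {v}")
        if len(self.n_per_study) != self.n_studies:
            raise InvalidConfigError("n_per_study length must equal n_studies")
        if len(self.case_fraction) != self.n_studies:
            raise InvalidConfigError("case_fraction length must equal n_studies")
        if any(n < 1 for n in self.n_per_study):
            raise InvalidConfigError("all study sizes must be >= 1")
        if any(not (0.0 < f < 1.0) for f in self.case_fraction):
            raise InvalidConfigError("case_fraction must lie strictly in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < min <= max <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise InvalidConfigError("ld_rho must lie in [0, 1)")
        for name in ("weight_sparsity", "cross_tissue_sharing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.n_genes * self.snps_per_gene > self.n_variants:
            raise InvalidConfigError(
                "n_genes * snps_per_gene exceeds n_variants; "
                "cannot place non-overlapping cis windows"
            )
        if self.n_causal_genes > self.n_genes:
            raise InvalidConfigError("n_causal_genes exceeds n_genes")

    @property
    def tissues(self) -> list[str]:
        """Tissue labels; the first half (rounded up) are brain tissues."""
        n_brain = (self.n_tissues + 1) // 2
        names = [f"{BRAIN_PREFIX}_{i:02d}" for i in range(n_brain)]
        names += [f"other_{i:02d}" for i in range(self.n_tissues - n_brain)]
        return names

    @property
    def causal_tissue(self) -> str:
        return self.tissues[0]


@dataclass
class SyntheticCohort:
    """One study: dosages, binary phenotype, covariates, and its label."""

    dosages: DosageMatrix
    phenotype: np.ndarray
    covariates: pd.DataFrame
    study_id: str

    def __post_init__(self) -> None:
        n = self.dosages.n_samples
        if len(self.phenotype) != n or len(self.covariates) != n:
            raise InvalidInputError("phenotype/covariates misaligned with dosages")
        if np.any(~np.isin(self.phenotype, (0, 1))):
            raise InvalidInputError("phenotype must be binary with no missing")

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())


@dataclass
class TruthRecord:
    """Ground truth of the simulated liability model."""

    causal_genes: set[str]
    liability_effects: dict[str, float]
    causal_tissue: str
    intercept: float = float("nan")

    def effect(self, gene: str) -> float:
        return self.liability_effects.get(gene, 0.0)


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def simulate_variant_table(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Shared variant scaffold: positions, alleles, target MAF, simulated R².

    Imputation R² is Uniform(0.3, 1.0) so a downstream R² > 0.5 filter has
    nonzero effect.  All variants sit on one chromosome, 5 kb apart.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _K_VARIANTS)
    m = config.n_variants
    lo, hi = config.maf_range
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": 10_000 + 5_000 * np.arange(m),
            "ref": [p[0] for p in pairs],
            "alt": [p[1] for p in pairs],
            "rsid": [f"rs{100000 + i}" for i in range(m)],
            "maf": rng.uniform(lo, hi, m),
            "r2": rng.uniform(0.3, 1.0, m),
        }
    )


def simulate_genotypes(
    config: SimulationConfig,
    seed: int | None = None,
    study: int = 0,
    n: int | None = None,
    variant_table: pd.DataFrame | None = None,
) -> DosageMatrix:
    """Draw a study's dosage matrix from the copula AR(1) haplotype model.

    Dosages are the sum of two independent haplotypes; each haplotype carries
    the alt allele where its latent AR(1) normal falls below the MAF
    quantile.  The returned metadata carries the realized (sample) MAF.
    """
    seed = config.seed if seed is None else seed
    if variant_table is None:
        variant_table = simulate_variant_table(config, seed)
    n = config.n_per_study[study] if n is None else n
    rng = _rng(seed, _K_HAPLO, study)
    m = len(variant_table)
    rho = config.ld_rho
    thr = norm.ppf(variant_table["maf"].to_numpy())

    dosage = np.zeros((n, m))
    scale = np.sqrt(1.0 - rho**2)
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        for _hap in range(2):
            z = np.empty((n, width))
            z[:, 0] = rng.standard_normal(n)
            eps = rng.standard_normal((n, width - 1)) if width > 1 else None
            for j in range(1, width):
                z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
            dosage[:, start:stop] += (z < thr[start:stop]).astype(float)

    meta = variant_table.copy()
    freq = dosage.mean(axis=0) / 2.0
    meta["maf"] = np.minimum(freq, 1.0 - freq)
    sample_ids = [f"S{study}_{i:05d}" for i in range(n)]
    return DosageMatrix(values=dosage, variant_meta=meta, sample_ids=sample_ids)


def simulate_weight_models(
    variant_table: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[WeightModel]:
    """Sparse cis-eQTL weight models for every gene x tissue.

    Gene g's cis window is the g-th block of ``snps_per_gene`` consecutive
    variants.  In the causal tissue each model has a dominant lead eQTL
    (|w| ~ N(1, 0.2), random sign) plus secondary weights of magnitude
    (0.1 + |N(0, 0.05)|) x |lead| with random sign, each present with
    probability ``weight_sparsity`` (at least one secondary is forced so no
    model is single-variant; secondaries scale with the lead, sharing the
    locus effect scale, and their magnitude floor mirrors trained sparse
    models, which threshold out negligible effects).  Other tissues carry each causal
    weight with probability ``cross_tissue_sharing``, scaled by a per-tissue
    factor N(1, tissue_factor_sd).  ``weight_sparsity = 0`` yields empty
    models everywhere.

    Effect alleles are recorded explicitly: a random ~20% of entries are
    expressed on the ref allele (weight negated), exercising downstream
    harmonization without changing the model.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _K_WEIGHTS)
    spg = config.snps_per_gene
    if config.n_genes * spg > len(variant_table):
        raise InvalidConfigError("not enough variants for non-overlapping cis windows")
    tissues = config.tissues
    factors = {
        t: (1.0 if i == 0 else rng.normal(1.0, config.tissue_factor_sd))
        for i, t in enumerate(tissues)
    }
    models: list[WeightModel] = []
    for g in range(config.n_genes):
        gene = f"G{g:04d}"
        window = variant_table.iloc[g * spg : (g + 1) * spg].reset_index(drop=True)
        tss = int(window["pos"].iloc[0])
        chrom = str(window["chrom"].iloc[0])

        causal_w = np.zeros(spg)
        if config.weight_sparsity > 0 and spg >= 1:
            lead = int(rng.integers(0, spg))
            causal_w[lead] = rng.choice([-1.0, 1.0]) * rng.normal(1.0, 0.2)
            others = [j for j in range(spg) if j != lead]
            chosen = [j for j in others if rng.random() < config.weight_sparsity]
            if not chosen and others:
                chosen = [others[int(rng.integers(0, len(others)))]]
            for j in chosen:
                causal_w[j] = rng.choice([-1.0, 1.0]) * (
                    0.1 + abs(rng.normal(0.0, 0.05))
                ) * abs(causal_w[lead])

        for t in tissues:
            if t == config.causal_tissue:
                w = causal_w.copy()
            else:
                keep = rng.random(spg) < config.cross_tissue_sharing
                w = np.where(keep, causal_w * factors[t], 0.0)
            nz = np.flatnonzero(w)
            ent = window.loc[nz, ["rsid", "chrom", "pos", "ref", "alt"]].copy()
            weights = w[nz]
            on_ref = rng.random(len(nz)) < 0.2
            ent["effect_allele"] = np.where(
                on_ref, ent["ref"].to_numpy(), ent["alt"].to_numpy()
            )
            ent["weight"] = np.where(on_ref, -weights, weights)
            models.append(
                WeightModel(
                    gene=gene,
                    tissue=t,
                    gene_chrom=chrom,
                    gene_tss=tss,
                    entries=ent.reset_index(drop=True),
                )
            )
    return models


def make_truth(
    config: SimulationConfig,
    seed: int | None = None,
    effects: dict[str, float] | None = None,
) -> TruthRecord:
    """Pick causal genes and liability effects (or accept them explicitly)."""
    seed = config.seed if seed is None else seed
    if effects is None:
        rng = _rng(seed, _K_TRUTH)
        genes = [f"G{g:04d}" for g in range(config.n_genes)]
        causal = rng.choice(genes, size=config.n_causal_genes, replace=False)
        effects = {g: float(rng.normal(0.0, config.effect_sd)) for g in causal}
    return TruthRecord(
        causal_genes=set(effects),
        liability_effects=dict(effects),
        causal_tissue=config.causal_tissue,
    )


def _simulate_covariates(
    config: SimulationConfig, n: int, seed: int, study: int
) -> pd.DataFrame:
    """Sex ~ Bernoulli(0.5); age ~ N(75, 8) truncated to [60, 95]; PCs ~ N(0,1)."""
    rng = _rng(seed, _K_COVAR, study)
    a, b = (60 - 75) / 8.0, (95 - 75) / 8.0
    cov = {
        "SEX": rng.integers(0, 2, n).astype(float),
        "AGE": truncnorm.rvs(a, b, loc=75, scale=8, size=n, random_state=rng),
    }
    for k in range(config.n_genetic_pcs):
        cov[f"PC{k + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def true_grex(
    dosages: DosageMatrix,
    weight_models: list[WeightModel],
    causal_tissue: str,
) -> GReXMatrix:
    """Causal-tissue GReX on the unfiltered dosage set (the truth signal)."""
    causal_models = [m for m in weight_models if m.tissue == causal_tissue]
    return impute_grex(dosages, causal_models)


def simulate_phenotype(
    cohort_genotypes: DosageMatrix,
    weight_models: list[WeightModel],
    truth: TruthRecord,
    config: SimulationConfig,
    seed: int | None = None,
    study: int = 0,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Draw case-control status from the logistic liability model.

    P(case_i) = expit(alpha + sum_g beta_g GReX_ig(causal tissue)
                      + g_sex sex_i + g_age age'_i)

    with age standardized before use.  The intercept alpha is found by
    bisection so the expected case fraction matches the study target to
    within 1e-6.  Returns (phenotype, alpha, covariates).
    """
    seed = config.seed if seed is None else seed
    n = cohort_genotypes.n_samples
    if covariates is None:
        covariates = _simulate_covariates(config, n, seed, study)

    eta = np.zeros(n)
    if truth.causal_genes:
        grex = true_grex(cohort_genotypes, weight_models, truth.causal_tissue)
        present = {g for g, _ in grex.values.columns}
        if truth.causal_genes - present - {g for g in truth.causal_genes if truth.effect(g) == 0}:
            missing = truth.causal_genes - present
            if any(truth.effect(g) != 0 for g in missing):
                raise InvalidInputError(
                    f"causal genes {sorted(missing)} lack {truth.causal_tissue} models"
                )
        for gene in sorted(truth.causal_genes):
            if gene in present and truth.effect(gene) != 0.0:
                eta += truth.effect(gene) * grex.values[
                    (gene, truth.causal_tissue)
                ].to_numpy()

    g_sex, g_age = config.covar_effects
    age = covariates["AGE"].to_numpy()
    age_std = (age - age.mean()) / age.std()
    eta += g_sex * covariates["SEX"].to_numpy() + g_age * age_std

    target = config.case_fraction[study]

    def excess(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - target)

    lo, hi = -30.0, 30.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise InvalidConfigError(
            f"cannot bracket intercept for case fraction {target}: "
            f"mean liability range [{excess(lo) + target:.3g}, {excess(hi) + target:.3g}]"
        )
    alpha = brentq(excess, lo, hi, xtol=1e-9)
    assert abs(excess(alpha)) < 1e-6

    rng = _rng(seed, _K_PHENO, study)
    y = (rng.random(n) < expit(alpha + eta)).astype(int)
    return y, float(alpha), covariates


def simulate_cohort(
    config: SimulationConfig,
    weight_models: list[WeightModel],
    truth: TruthRecord,
    seed: int | None = None,
    study: int = 0,
    variant_table: pd.DataFrame | None = None,
) -> SyntheticCohort:
    """One study end to end: genotypes, covariates, phenotype."""
    seed = config.seed if seed is None else seed
    dosages = simulate_genotypes(config, seed, study=study, variant_table=variant_table)
    y, alpha, covariates = simulate_phenotype(
        dosages, weight_models, truth, config, seed, study=study
    )
    truth.intercept = alpha
    return SyntheticCohort(
        dosages=dosages,
        phenotype=y,
        covariates=covariates,
        study_id=f"study_{study}",
    )


def simulate_study_set(
    config: SimulationConfig, seed: int | None = None,
    effects: dict[str, float] | None = None,
) -> tuple[list[SyntheticCohort], list[WeightModel], TruthRecord]:
    """All studies of one experiment, sharing variant map, models, and truth."""
    seed = config.seed if seed is None else seed
    vt = simulate_variant_table(config, seed)
    models = simulate_weight_models(vt, config, seed)
    truth = make_truth(config, seed, effects=effects)
    cohorts = [
        simulate_cohort(config, models, truth, seed, study=s, variant_table=vt)
        for s in range(config.n_studies)
    ]
    return cohorts, models, truth


# ---------------------------------------------------------------------------
# per-variant GWAS and LD reference


def logistic_gwas(
    dosage_col: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[float, float, bool]:
    """Plain (unpenalized) logistic Wald test for one variant.

    Newton-Raphson on the ordinary log-likelihood; returns (beta, se,
    converged) for the dosage term.  Kept deliberately separate from the
    Firth machinery: consortium GWAS summary statistics come from standard
    logistic regression.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), covariates, dosage_col])
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info = (X * W[:, None]).T @ X
        try:
            beta = beta + np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta)) > 50:  # separation guard
            break
    p = expit(X @ beta)
    W = p * (1 - p)
    info = (X * W[:, None]).T @ X
    try:
        var = np.linalg.inv(info)[-1, -1]
    except np.linalg.LinAlgError:
        return float("nan"), float("nan"), False
    return float(beta[-1]), float(np.sqrt(var)), converged


def compute_gwas_summary(
    cohort: SyntheticCohort,
    weight_models: list[WeightModel] | None = None,
    covariate_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, "LDReference"]:
    """Per-variant logistic Wald summary statistics plus a per-gene LD reference.

    The summary table carries SNP, CHR, POS, A1 (effect = alt), A2, FRQ,
    BETA, SE, Z, P, N plus the simulated MAF/R² fields the summary-mode
    filter acts on.  Monomorphic variants get z = 0 with ``monomorphic =
    True`` and are excluded from the LD covariance.
    """
    from .summary import LDReference

    y = cohort.phenotype.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidInputError("phenotype must be binary")
    cov_cols = covariate_cols or list(cohort.covariates.columns)
    C = cohort.covariates[cov_cols].to_numpy(dtype=float)
    D = cohort.dosages.values
    meta = cohort.dosages.variant_meta
    n, m = D.shape

    rows = []
    for j in range(m):
        d = D[:, j]
        frq = d.mean() / 2.0
        mono = d.min() == d.max()
        if mono:
            beta, se, z, p = 0.0, float("nan"), 0.0, 1.0
        else:
            beta, se, _ = logistic_gwas(d, y, C)
            z = beta / se if se > 0 else 0.0
            p = float(2.0 * norm.sf(abs(z)))
        rows.append(
            (
                meta["rsid"].iloc[j], meta["chrom"].iloc[j], int(meta["pos"].iloc[j]),
                meta["alt"].iloc[j], meta["ref"].iloc[j], float(frq),
                beta, se, float(z), p, n, float(meta["maf"].iloc[j]),
                float(meta["r2"].iloc[j]), bool(mono),
            )
        )
    stats = pd.DataFrame(
        rows,
        columns=[
            "SNP", "CHR", "POS", "A1", "A2", "FRQ", "BETA", "SE", "Z", "P",
            "N", "MAF", "R2", "monomorphic",
        ],
    )
    ld = build_ld_reference(cohort.dosages, weight_models or [])
    return stats, ld


def build_ld_reference(
    dosages: DosageMatrix, weight_models: list[WeightModel]
) -> "LDReference":
    """Empirical per-gene dosage covariance of each gene's model variants.

    The cohort supplying ``dosages`` plays the "reference population" role;
    monomorphic variants are excluded.  Variants are pooled over all tissues'
    models of a gene so cross-tissue combination can reuse one matrix.
    """
    from .summary import LDReference

    meta = dosages.variant_meta
    poly = dosages.values.std(axis=0) > 0
    rsid_to_col = {
        str(r): i for i, r in enumerate(meta["rsid"]) if poly[i]
    }
    per_gene: dict[str, list[str]] = {}
    for model in weight_models:
        lst = per_gene.setdefault(model.gene, [])
        for r in model.entries["rsid"]:
            if str(r) in rsid_to_col and str(r) not in lst:
                lst.append(str(r))
    covs = {}
    for gene, rsids in per_gene.items():
        if not rsids:
            continue
        cols = [rsid_to_col[r] for r in rsids]
        sub = dosages.values[:, cols]
        gamma = np.cov(sub, rowvar=False, ddof=1)
        gamma = np.atleast_2d(gamma)
        covs[gene] = (rsids, gamma)
    return LDReference(covs)
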