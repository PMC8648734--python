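# Methods

`grexpipe` implements a gene-level association study for case-control
traits built on genetically regulated expression (GReX): the component of a
gene's expression predictable from germline genotype through tissue-specific
eQTL weight models.  The pipeline covers imputation of GReX from dosages,
Firth-penalized single-tissue and conditional association, a cross-tissue
principal-component likelihood-ratio test, summary-statistic association
against an LD reference, sample-size-weighted meta-analysis with
Benjamini–Hochberg FDR control, and post-hoc evaluation statistics.  A
synthetic-cohort generator with known ground truth makes every stage
testable without access to consortium genotype data.

## GReX imputation

For individual *i* and gene *g* in tissue *t*,

    GReX_ig = Σ_k w_kg · d'_ik

where `w` are the model weights and `d'` is the alt-allele dosage, used as
`2 − d` when the model's effect allele is the reference allele.
Harmonization matches model entries to dosage variants by (chrom, pos,
unordered allele pair), falling back to rsid; entries absent from the
dosage set contribute zero (no mean imputation), and per-model coverage
(n_snps_used / n_snps_in_model) is reported so low-coverage genes can be
filtered.  GReX values enter the association tests raw (unstandardized),
matching the upstream imputation tool's convention; a `standardize` flag
exists for sensitivity checks.  Variant QC keeps MAF > 0.05 and imputation
R² > 0.5 (strict inequalities) for individual-level data; summary-mode
filtering removes MAF < 0.01 or R² < 0.5.

## Firth-penalized logistic regression

Case-control cohorts with strong imbalance bias ordinary logistic maximum
likelihood and can make it diverge under separation.  All association fits
therefore maximize the Jeffreys-penalized likelihood
`l*(β) = l(β) + ½ log det I(β)` by Newton iteration on the modified score
`U*_j = Σ_i (y_i − p_i + h_i(½ − p_i)) x_ij`, with step-halving (up to 5
per iteration), convergence at max|U*| < 1e-8, and a 50-iteration cap.
These controls match common Firth implementations and guarantee monotone
penalized-likelihood ascent.

P-values default to the profile penalized likelihood ratio (the default of
the reference R implementation), with Wald available.  A detail that
matters: the "reduced" fit fixes the tested coefficients at zero **under
the full design's penalty** rather than dropping the columns.  Dropping
columns changes the dimension of `I(β)`, the log-determinant terms no
longer cancel, and the statistic is shifted under the null — with design
matrices of a few hundred rows the shift is large enough to destroy
chi-square calibration.  The profile form restores it (verified by
simulation: empirical type-I error at nominal 0.05 lies in [0.03, 0.07]
for both the single-tissue test and the cross-tissue LRT at n = 1000 with
20% cases).  The signed z fed to meta-analysis is reconstructed as
`sign(β)·Φ⁻¹(1 − p/2)` so both p-value methods feed it uniformly.

Covariates are sex, age (a single column mixing age-at-onset for cases and
age-at-last-exam for controls), and genetic PCs (default 4).

## Conditional analysis and tag SNPs

Conditional tests add one covariate — a known risk SNP's dosage or another
gene's GReX — and re-test.  A conditioning column with |r| > 0.999 against
the tested GReX raises a collinearity error rather than returning an
unstable fit.  When an index risk SNP is absent from the dosage set,
`select_tag_snp` returns the available variant with maximal squared dosage
correlation, requiring r² > 0.6, breaking ties toward the variant nearest
the index position and then the lowest position.

## Cross-tissue test

Genes with models in ≥ 5 tissues (all-tissue scope) or ≥ 3 brain tissues
(brain scope) are eligible.  Per gene, tissue columns are centered and
unit-scaled (correlation-matrix PCA — prevents high-variance tissues from
dominating and makes the variance rule scale-free), and the smallest
number of components whose cumulative explained variance reaches 0.8 is
retained (ties break toward fewer components).  Components are oriented so
the largest-magnitude loading is positive (reporting stability only).  The
test statistic is `L = 2(ln L_full − ln L_reduced)` from Firth fits with
and without the component scores, referred to chi-square with df = number
of components.  PCA runs per study and results are meta-analyzed, like the
single-tissue arm.

## Summary-statistic association

From per-variant GWAS summary z-scores and a per-gene dosage covariance Γ
(the LD reference), the gene-level statistic is

    z_g = Σ_l w_l (σ_l / σ_g) z_l,   σ_g² = Σ_l Σ_m w_l w_m Γ_lm .

Weights and z-scores are both re-expressed on the alt allele of the model's
variant record — the convention Γ is computed on — which makes the result
invariant to how the GWAS file happens to code each variant.  The
summary-mode cross-tissue combination eigendecomposes the
predicted-expression correlation across tissues (computable from weights
and Γ alone), discards components with condition number above 30 (the
upstream tool's convention, exposed as a flag), and refers the quadratic
form of the rotated z-vector to chi-square with one df per retained
component — the large-reference-panel limit of the F-test, appropriate
here because synthetic reference panels are large.

Per-variant GWAS inside the generator uses ordinary (non-Firth) logistic
Wald tests via a vectorized Newton solver, matching how consortium summary
statistics are produced in practice; it is validated against an
independent textbook implementation in the tests.

## Meta-analysis and FDR

Per-study signed z-scores combine as `Z = Σ √N_i z_i / √(Σ N_i)` — the
sample-size weighting of the standard meta-analysis tool.  Feeding the
published per-study rows for the five strongest novel genes of the
motivating study through this formula reproduces the published combined
z-scores to ±0.005 (the printed inputs carry 3 decimals), whereas the
alternative N-weighting `Σ N_i z_i / √(Σ N_i²)` misses by up to 0.11;
the √N scheme is therefore the default, with N-weighting behind a flag.
Two-sided p throughout; no duplicate-study protection is claimed.
Benjamini–Hochberg runs over one pooled family (single- plus cross-tissue
tests); the step-up rule is implemented directly so that it matches the
textbook definition bit-for-bit, and is cross-checked against statsmodels.
Novelty annotation flags a gene as known-region iff its transcription
start lies within ±10 Mb of any known risk SNP on the same chromosome
(boundary inclusive; chromosome labels normalized).

## Evaluation statistics

- **Storey π1** (true-positive rate): π̂0(λ) = #{p>λ}/(m(1−λ)) over
  λ ∈ {0.05, …, 0.95}; the default smoother fits a cubic trend and
  evaluates it at max λ.  The cubic is fit by weighted least squares with
  weights ∝ (1−λ), since var π̂0(λ) grows like 1/(1−λ); this tempers the
  extrapolation noise of the right-hand grid points.  A fixed-λ = 0.5 mode
  is retained for small sets.
- **Median-based Mendelian randomization**: per-instrument Wald ratios
  `r_l = β_out,l / β_exp,l`; simple median or inverse-variance-weighted
  median (delta-method ratio variances); SE by parametric bootstrap
  resampling the betas from their stated normal errors (seed mandatory);
  p by normal approximation.  Robust to up to ~50% invalid instruments.
- **Enrichment ratio**: proportion of heritability over proportion of
  SNPs, with optional SE propagation.  The LD-score regression machinery
  that produces the proportions is an external tool and is not
  re-implemented; the ratio arithmetic consumes its outputs.
- **Method concordance**: r² of log-transformed p-values over shared
  (gene, tissue) tests plus counts of tests significant (per-method BH)
  in exactly one arm.

## Synthetic-data generator

The generator emulates a multi-study consortium design: several studies
with unequal N and case:control imbalance (defaults: 1500/1000/2500
individuals at case fractions 0.35/0.20/0.50), a shared variant map, and
per-study GWAS summary statistics with a matching LD reference.

- **Genotypes**: two haplotypes per individual from a Gaussian-copula
  AR(1) block process (within-block latent correlation `ld_rho`, default
  0.85, block = one cis window), thresholded at each variant's MAF
  quantile (MAF ~ Uniform(0.1, 0.5)).  Dosages are integer allele counts
  in {0, 1, 2}; imputation uncertainty is represented only by a simulated
  per-variant R² ~ Uniform(0.3, 1.0), which gives the R² > 0.5 filter real
  effect.  Thresholding attenuates the latent correlation, so realized
  dosage r² is tuned empirically per scenario (a mapping measured in the
  tests), and adjacent-pair r² rises monotonically with `ld_rho`.
- **Weight models**: gene g's cis window is a block of `snps_per_gene`
  consecutive variants.  The causal-tissue model has a dominant lead eQTL
  (|w| ~ N(1, 0.2), random sign) plus secondary weights of magnitude
  (0.1 + |N(0, 0.05)|)·|lead| present with probability `weight_sparsity`,
  at least one forced.  This mirrors trained sparse models: a lead variant
  carries most of the signal, secondaries are bounded away from zero
  (regularization removes negligible effects) and share the locus effect
  scale.  Setting sparsity to 0 yields empty models.  Non-causal tissues
  carry only the shared subset of the causal tissue's weights (each copied
  with probability `cross_tissue_sharing`, scaled by a per-tissue factor
  N(1, `tissue_factor_sd`)); with sharing = 1 and factor SD = 0, all
  tissues are identical by construction.  About 20% of entries are
  recorded on the ref allele (weight negated) to exercise harmonization.
- **Phenotype**: P(case) = logistic(α + Σ_g β_g GReX_g(causal tissue) +
  γ_sex·sex + γ_age·age′), with age ~ N(75, 8) truncated to [60, 95]
  (standardized before use; a late-onset design where cases and controls
  share the age distribution), sex ~ Bernoulli(0.5), and genetic PCs as
  standard-normal covariate columns.  The intercept α is found by
  bisection so the expected case fraction matches the study target within
  1e-6.
- **Determinism**: every draw flows from one integer seed through named
  `SeedSequence` spawn keys (variant map, weights, truth, and per-study
  haplotype/covariate/phenotype streams), so any module can be re-run
  bit-identically in isolation.

What the generator does **not** emulate: real human LD panels, population
structure or admixture, relatedness, strand ambiguity across datasets, the
X chromosome, genotyping error, or age-dependent expression.  Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under a faithful but idealized genetic architecture,
not performance on real consortium data.

## Designed study conditions in the test suite

Stochastic guarantees are checked at fixed desk-scale problem sizes chosen
so each run stays within a few CPU-minutes:

- Null calibration: 10 replicate studies × 250 null genes at n = 1000
  with 20% cases (the imbalance regime that motivates the Firth
  correction), pooled to ≥ 2000 genes per test.
- Causal recovery and conditional analysis: 20 replicates of two studies
  × 2500 individuals, 40 genes, one causal gene at β = 0.4.  Loci are
  two-variant high-LD blocks (`ld_rho` = 0.97, MAF ∈ [0.35, 0.5]) so each
  gene's signal is carried by its dominant lead eQTL with a weak, bounded
  secondary: conditioning on the lead removes nearly all signal without
  triggering the collinearity guard.  This is the regime the conditional
  analysis is designed to detect (a gene whose association is fully
  explained by a known variant); the complementary regime — an independent
  second mechanism that survives conditioning — is tested separately.
- Individual-vs-summary concordance: one study of 3000 with 100 genes ×
  3 tissues, 8 causal genes; the summary arm is run once with the
  in-cohort LD reference and once with an LD reference from an
  independent cohort of the same design, which strictly lowers the log-p
  concordance — the power cost of external LD panels.

## Known limitations

- The Firth solver targets dense designs with tens of covariates; it does
  not exploit sparsity and is not suitable for genome-wide variant-level
  Firth scans.
- The summary-mode cross-tissue statistic assumes the LD reference is
  large (chi-square rather than F reference).
- `combine_z` treats per-study z-scores as independent; overlapping
  samples between studies are the caller's responsibility.
- The bootstrap SE in `mr_median` is parametric; it inherits the stated
  per-instrument standard errors and ignores winner's-curse selection of
  instruments.
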