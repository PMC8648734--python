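"""Post-hoc evaluation statistics.

Storey's true-positive rate pi1 per tissue, median-based Mendelian
randomization over eQTL instruments, heritability-enrichment ratio
arithmetic, and cross-method concordance of significance calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidInputError
from .meta import bh_adjust

__all__ = [
    "Pi1Result",
    "MRResult",
    "EnrichmentResult",
    "ConcordanceResult",
    "storey_pi1",
    "mr_median",
    "enrichment_ratio",
    "method_concordance",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class Pi1Result:
    pi0_hat: float
    pi1: float
    lambda_grid: np.ndarray
    n_tests: int
    mode: str


@dataclass
class MRResult:
    estimate: float
    se: float
    p: float
    n_instruments: int
    method: str
    n_boot: int
    seed: int


@dataclass
class EnrichmentResult:
    prop_h2: float
    prop_snps: float
    enrichment: float
    se_enrichment: float | None = None
    p: float | None = None


@dataclass
class ConcordanceResult:
    r2_logp: float
    n_only_a: int
    n_only_b: int
    n_common: int
    n_tests: int


def storey_pi1(
    pvals,
    lambda_grid=None,
    mode: str = "smoother",
) -> Pi1Result:
    """Estimated proportion of true alternatives among a set of p-values.

    pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)); the ``smoother``
    mode fits a cubic trend to pi0_hat over the lambda grid and evaluates it
    at the largest lambda (the standard extrapolation), while ``fixed`` uses
    lambda = 0.5 directly.  pi1 = clamp(1 - pi0_hat, 0, 1).

    The cubic is fit by weighted least squares with weights proportional to
    (1 - lambda): var pi0_hat(lambda) grows like 1/(1 - lambda), and the
    inverse-variance weighting tempers the noise of the right-hand grid
    points that dominate the extrapolation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value set")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise InvalidInputError("p-values must lie in [0, 1]")
    if p.size < 100:
        warnings.warn(
            f"only {p.size} p-values; pi1 estimate may be unstable", stacklevel=2
        )
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if mode == "fixed":
        lam = 0.5
        pi0 = np.mean(p > lam) / (1.0 - lam)
    elif mode == "smoother":
        pi0_grid = np.array(
            [np.mean(p > lam) / (1.0 - lam) for lam in grid]
        )
        coeffs = np.polyfit(grid, pi0_grid, deg=3, w=np.sqrt(1.0 - grid))
        pi0 = float(np.polyval(coeffs, grid.max()))
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Result(
        pi0_hat=pi0, pi1=1.0 - pi0, lambda_grid=grid, n_tests=p.size, mode=mode
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (weights normalized to sum 1)."""
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def mr_median(
    beta_exposure,
    se_exposure,
    beta_outcome,
    se_outcome,
    weighted: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Median-based Mendelian randomization over per-instrument Wald ratios.

    Each instrument's causal-effect estimate is r_l = beta_outcome_l /
    beta_exposure_l; the point estimate is the simple median (robust to up
    to 50% invalid instruments) or the inverse-variance-weighted median.
    The standard error comes from a parametric bootstrap resampling the
    per-instrument betas from their stated normal errors; p is the normal
    approximation 2 Phi(-|estimate/se|).
    """
    bx = np.asarray(beta_exposure, float)
    sx = np.asarray(se_exposure, float)
    by = np.asarray(beta_outcome, float)
    sy = np.asarray(se_outcome, float)
    if not (bx.shape == sx.shape == by.shape == sy.shape):
        raise InvalidInputError("instrument vectors must share a length")
    if bx.size < 3:
        raise InvalidInputError(f"need >= 3 instruments, got {bx.size}")
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise InvalidInputError(
            f"zero exposure effect for instrument(s) {zero.tolist()}; "
            "Wald ratio undefined"
        )

    def estimate(bx_, by_):
        r = by_ / bx_
        if weighted:
            # delta-method variance of each Wald ratio
            var = sy**2 / bx_**2 + by_**2 * sx**2 / bx_**4
            return _weighted_median(r, 1.0 / var)
        return float(np.median(r))

    est = estimate(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        boots[b] = estimate(bx_b, by_b)
    se = float(boots.std(ddof=1))
    if se == 0:
        p = 0.0 if est != 0 else 1.0
    else:
        p = float(2.0 * norm.sf(abs(est) / se))
    return MRResult(
        estimate=est,
        se=se,
        p=p,
        n_instruments=bx.size,
        method="weighted_median" if weighted else "simple_median",
        n_boot=n_boot,
        seed=seed,
    )


def enrichment_ratio(
    prop_h2: float,
    prop_snps: float,
    se_h2: float | None = None,
    percent: bool = False,
) -> EnrichmentResult:
    """Heritability enrichment = proportion of h2 / proportion of SNPs.

    With ``percent=True`` inputs are on the 0-100 scale (the ratio is
    unit-invariant).  If the h2 proportion's standard error is supplied,
    se_enrichment = se_h2 / prop_snps and p tests enrichment != 1 by normal
    approximation.
    """
    scale = 100.0 if percent else 1.0
    h2 = prop_h2 / scale
    snps = prop_snps / scale
    if snps == 0:
        raise InvalidInputError("prop_snps must be > 0")
    if not (0 <= h2 <= 1) or not (0 < snps <= 1):
        raise InvalidInputError("proportions must lie in [0, 1]")
    enr = h2 / snps
    se_e = p = None
    if se_h2 is not None:
        se_e = (se_h2 / scale) / snps
        p = float(2.0 * norm.sf(abs(enr - 1.0) / se_e)) if se_e > 0 else 0.0
    return EnrichmentResult(
        prop_h2=h2, prop_snps=snps, enrichment=enr, se_enrichment=se_e, p=p
    )


def method_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    fdr: float = 0.05,
    keys: tuple[str, ...] = ("GENE", "TISSUE"),
) -> ConcordanceResult:
    """Concordance of two association tables keyed by (gene, tissue).

    r² of log10 p over the shared tests, plus counts of tests significant
    (per-method BH at ``fdr``) in exactly one method and in both.
    """
    a = results_a[[*keys, "P"]].rename(columns={"P": "P_A"})
    b = results_b[[*keys, "P"]].rename(columns={"P": "P_B"})
    merged = a.merge(b, on=list(keys))
    if merged.empty:
        raise InvalidInputError("no shared (gene, tissue) tests between methods")
    la = np.log10(merged["P_A"].to_numpy())
    lb = np.log10(merged["P_B"].to_numpy())
    r2 = float(np.corrcoef(la, lb)[0, 1] ** 2)
    sig_a = bh_adjust(merged["P_A"].to_numpy(), q=fdr)["significant"].to_numpy()
    sig_b = bh_adjust(merged["P_B"].to_numpy(), q=fdr)["significant"].to_numpy()
    return ConcordanceResult(
        r2_logp=r2,
        n_only_a=int(np.sum(sig_a & ~sig_b)),
        n_only_b=int(np.sum(~sig_a & sig_b)),
        n_common=int(np.sum(sig_a & sig_b)),
        n_tests=len(merged),
    )
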