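"""Summary-statistic GReX association.

Reproduces, from per-variant GWAS summary statistics and an external LD
reference, the gene-level z-score that the individual-level pipeline
computes from raw dosages:

    z_g = sum_l w_l (sigma_l / sigma_g) z_l,
    sigma_g^2 = sum_l sum_m w_l w_m Gamma_lm,

where w are the model weights, z_l the per-variant GWAS z-scores (aligned
to the model's effect alleles), Gamma the dosage covariance of the model's
variants in a reference population, and sigma_l^2 its diagonal.  A
cross-tissue combination rotates the per-tissue z vector into the
eigenbasis of the predicted-expression correlation matrix, discards
ill-conditioned components, and refers the resulting quadratic form to
chi-square with one degree of freedom per retained component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .errors import (
    EmptyResultError,
    InvalidInputError,
    UntestableGeneError,
)
from .grex import WeightModel

__all__ = [
    "LDReference",
    "SummaryAssociation",
    "filter_summary",
    "spredixcan_z",
    "summary_cross_tissue",
]


@dataclass
class LDReference:
    """Per-gene variant list + dosage covariance Gamma (sigma_l^2 on the diagonal)."""

    covariances: dict[str, tuple[list[str], np.ndarray]]

    def __post_init__(self) -> None:
        for gene, (rsids, gamma) in self.covariances.items():
            gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
            if gamma.shape != (len(rsids), len(rsids)):
                raise InvalidInputError(f"LD matrix shape mismatch for {gene}")
            if not np.allclose(gamma, gamma.T, atol=1e-10):
                raise InvalidInputError(f"LD matrix for {gene} is not symmetric")
            self.covariances[gene] = (list(map(str, rsids)), gamma)

    def gene(self, gene: str) -> tuple[list[str], np.ndarray]:
        try:
            return self.covariances[gene]
        except KeyError as exc:
            from .errors import LookupError_

            raise LookupError_(f"gene {gene} absent from LD reference") from exc

    def genes(self) -> list[str]:
        return sorted(self.covariances)


@dataclass
class SummaryAssociation:
    gene: str
    tissue: str
    z: float
    p: float
    n_snps_used: int
    sigma_g: float


def filter_summary(
    stats: pd.DataFrame, maf_min: float = 0.01, r2_min: float = 0.5
) -> pd.DataFrame:
    """Remove low-frequency (MAF < maf_min) or low-quality (R² < r2_min) variants."""
    for col in ("MAF", "R2"):
        if col not in stats.columns:
            raise InvalidInputError(f"summary table lacks column {col}")
    keep = (stats["MAF"].to_numpy() >= maf_min) & (stats["R2"].to_numpy() >= r2_min)
    out = stats.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyResultError(
            f"no summary records pass MAF >= {maf_min} and R² >= {r2_min}"
        )
    return out


def _align_model_to_stats(
    model: WeightModel, stats: pd.DataFrame
) -> pd.DataFrame:
    """Match model entries to summary records by rsid, aligning effect alleles.

    Both the weight and the GWAS z are re-expressed on the model's alt
    allele — the convention the LD reference's dosage covariance is built
    on — so a summary record arriving with either allele coded gives the
    same gene-level statistic.  Irreconcilable allele pairs are dropped.
    """
    idx = {str(s): i for i, s in enumerate(stats["SNP"])}
    rows = []
    for e in model.entries.itertuples(index=False):
        i = idx.get(str(e.rsid))
        if i is None:
            continue
        a1, a2 = str(stats["A1"].iloc[i]), str(stats["A2"].iloc[i])
        alt = str(e.alt)
        if {a1, a2} != {str(e.ref), alt}:
            continue
        w = float(e.weight) if str(e.effect_allele) == alt else -float(e.weight)
        z = float(stats["Z"].iloc[i])
        if a1 != alt:
            z = -z
        rows.append((str(e.rsid), w, z))
    return pd.DataFrame(rows, columns=["rsid", "weight", "z"])


def spredixcan_z(
    model: WeightModel,
    stats: pd.DataFrame,
    ld: LDReference,
    var_tol: float = 1e-12,
) -> SummaryAssociation:
    """Gene-level association z from GWAS summary statistics and reference LD."""
    aligned = _align_model_to_stats(model, stats)
    rsids, gamma = ld.gene(model.gene)
    pos = {r: i for i, r in enumerate(rsids)}
    usable = aligned[aligned["rsid"].isin(pos)].reset_index(drop=True)
    if usable.empty:
        raise UntestableGeneError(
            f"{model.gene}@{model.tissue}: no model variant usable"
        )
    cols = [pos[r] for r in usable["rsid"]]
    G = gamma[np.ix_(cols, cols)]
    w = usable["weight"].to_numpy()
    zl = usable["z"].to_numpy()
    sigma_l = np.sqrt(np.clip(np.diag(G), 0.0, None))
    sigma_g2 = float(w @ G @ w)
    if sigma_g2 <= var_tol:
        raise UntestableGeneError(
            f"{model.gene}@{model.tissue}: predicted expression variance ~ 0"
        )
    sigma_g = float(np.sqrt(sigma_g2))
    z = float(np.sum(w * sigma_l * zl) / sigma_g)
    return SummaryAssociation(
        gene=model.gene,
        tissue=model.tissue,
        z=z,
        p=float(2.0 * norm.sf(abs(z))),
        n_snps_used=len(usable),
        sigma_g=sigma_g,
    )


def _predicted_expression_corr(
    models: list[WeightModel], ld: LDReference, var_tol: float = 1e-12
) -> tuple[np.ndarray, list[str]]:
    """Correlation of predicted expression across tissues, from weights and LD."""
    gene = models[0].gene
    rsids, gamma = ld.gene(gene)
    pos = {r: i for i, r in enumerate(rsids)}
    tissues, wvecs = [], []
    for m in models:
        w = np.zeros(len(rsids))
        ok = False
        for e in m.entries.itertuples(index=False):
            i = pos.get(str(e.rsid))
            if i is None:
                continue
            # express the weight on the alt allele: ref-allele weights negate
            wt = float(e.weight)
            if str(e.effect_allele) == str(e.ref):
                wt = -wt
            w[i] = wt
            ok = True
        if ok and w @ gamma @ w > var_tol:
            tissues.append(m.tissue)
            wvecs.append(w)
    if len(tissues) < 2:
        raise UntestableGeneError(f"{gene}: < 2 tissues with usable models")
    W = np.array(wvecs)
    C = W @ gamma @ W.T
    sd = np.sqrt(np.diag(C))
    corr = C / np.outer(sd, sd)
    return corr, tissues


def summary_cross_tissue(
    z_by_tissue: dict[str, float],
    models: list[WeightModel],
    ld: LDReference,
    condition_cutoff: float = 30.0,
) -> dict:
    """Cross-tissue quadratic combination of per-tissue summary z-scores.

    Eigendecomposes the predicted-expression correlation matrix across
    tissues, drops components whose condition number (lambda_max / lambda_i)
    exceeds ``condition_cutoff``, and refers
    ``sum_i (u_i' z)^2 / lambda_i`` over retained components to chi-square
    with df = number retained (the large-reference-panel limit of the
    F-test used by summary cross-tissue tools).
    """
    usable = [m for m in models if m.tissue in z_by_tissue]
    if len(usable) < 2:
        raise InvalidInputError("need >= 2 tissues with defined z")
    corr, tissues = _predicted_expression_corr(usable, ld)
    z = np.array([z_by_tissue[t] for t in tissues])
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 0:
        raise InvalidInputError("predicted-expression correlation not PSD")
    keep = vals > vals[0] / condition_cutoff
    k = int(keep.sum())
    proj = vecs[:, keep].T @ z
    stat = float(np.sum(proj**2 / vals[keep]))
    return {
        "gene": usable[0].gene,
        "n_tissues": len(tissues),
        "n_components": k,
        "statistic": stat,
        "p": float(chi2.sf(stat, df=k)),
    }
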