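"""Tissue-specific and conditional GReX association tests.

One Firth-penalized logistic fit per (gene, tissue) column of a GReX
matrix, with covariate adjustment for sex, age, and genetic principal
components.  Conditional analysis re-tests a gene after adding a known risk
SNP's dosage (or another gene's GReX) as a covariate, isolating signal
independent of the known locus; when the index SNP itself is unavailable a
tag SNP in strongest LD (r² above a threshold) stands in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CollinearityError, InvalidInputError
from .firth import coefficient_pvalue, fit_firth
from .grex import DosageMatrix, GReXMatrix, VariantKey

__all__ = [
    "TagSnpChoice",
    "assoc_single_tissue",
    "assoc_conditional",
    "select_tag_snp",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("SEX", "AGE")


@dataclass
class TagSnpChoice:
    index_snp: VariantKey
    chosen: VariantKey | None
    r2: float


def _base_design(covariates: pd.DataFrame, covariate_cols: list[str] | None):
    cols = list(covariate_cols) if covariate_cols else list(covariates.columns)
    for c in ("SEX", "AGE"):
        if c not in cols:
            raise InvalidInputError(f"covariates must include {c}")
    C = covariates[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(C)), C])


def _single_fit(
    base: np.ndarray,
    term_col: np.ndarray,
    y: np.ndarray,
    method: str,
    extra: np.ndarray | None = None,
):
    """Fit base [+ extra conditioning column] + term; test the last column."""
    parts = [base]
    if extra is not None:
        parts.append(extra.reshape(-1, 1))
    parts.append(term_col.reshape(-1, 1))
    X = np.column_stack(parts)
    fit = fit_firth(X, y)
    term = X.shape[1] - 1
    z, p = coefficient_pvalue(fit, term, method=method)
    return fit, term, z, p


def assoc_single_tissue(
    grex: GReXMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    method: str = "penalized_lr",
    covariate_cols: list[str] | None = None,
    study: str = "study_0",
    standardize: bool = False,
) -> pd.DataFrame:
    """Test every (gene, tissue) GReX column against case-control status.

    Returns one row per testable column: GENE, TISSUE, STUDY, BETA, SE, Z,
    P, N, N_CASES, METHOD, CONDITIONING.  Constant GReX columns are
    untestable and skipped with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    base = _base_design(covariates, covariate_cols)

    rows = []
    for gene, tissue in grex.values.columns:
        g = grex.values[(gene, tissue)].to_numpy(dtype=float)
        if g.std() == 0:
            warnings.warn(
                f"constant GReX column {gene}@{tissue}; untestable, skipped",
                stacklevel=2,
            )
            continue
        if standardize:
            g = (g - g.mean()) / g.std()
        fit, term, z, p = _single_fit(base, g, y, method)
        rows.append(
            {
                "GENE": gene,
                "TISSUE": tissue,
                "STUDY": study,
                "BETA": fit.coef[term],
                "SE": fit.se[term],
                "Z": z,
                "P": p,
                "N": len(y),
                "N_CASES": int(y.sum()),
                "METHOD": method,
                "CONDITIONING": "",
            }
        )
    return pd.DataFrame(rows)


def assoc_conditional(
    grex: GReXMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    gene: str,
    tissue: str,
    conditioning: np.ndarray,
    conditioning_label: str = "conditioned",
    method: str = "penalized_lr",
    covariate_cols: list[str] | None = None,
    study: str = "study_0",
    collinearity_r: float = 0.999,
) -> pd.Series:
    """Re-test one gene with an extra conditioning covariate.

    ``conditioning`` is a sample-aligned column: a known risk SNP's dosage
    or the GReX of the gene reported for that SNP.  Raises
    ``CollinearityError`` when the conditioning column is numerically
    indistinguishable from the tested GReX (|r| > 0.999).
    """
    y = np.asarray(phenotype, dtype=float)
    cond = np.asarray(conditioning, dtype=float)
    if len(cond) != len(y):
        raise InvalidInputError("conditioning column misaligned with samples")
    g = grex.values[(gene, tissue)].to_numpy(dtype=float)
    if cond.std() > 0 and g.std() > 0:
        r = float(np.corrcoef(g, cond)[0, 1])
        if abs(r) > collinearity_r:
            raise CollinearityError(
                f"conditioning column collinear with {gene}@{tissue} (|r|={abs(r):.4f})"
            )
    base = _base_design(covariates, covariate_cols)
    fit, term, z, p = _single_fit(base, g, y, method, extra=cond)
    return pd.Series(
        {
            "GENE": gene,
            "TISSUE": tissue,
            "STUDY": study,
            "BETA": fit.coef[term],
            "SE": fit.se[term],
            "Z": z,
            "P": p,
            "N": len(y),
            "N_CASES": int(y.sum()),
            "METHOD": method,
            "CONDITIONING": conditioning_label,
        }
    )


def select_tag_snp(
    index: VariantKey,
    reference: DosageMatrix,
    r2_min: float = 0.6,
    candidates: list[VariantKey] | None = None,
) -> TagSnpChoice:
    """Choose the available variant in strongest LD with an index risk SNP.

    ``reference`` plays the LD-panel role and must contain the index
    variant; ``candidates`` restricts the searchable variants (defaults to
    every reference variant).  Returns ``chosen=None`` when no candidate
    reaches r² > ``r2_min``.  Ties break to the variant nearest the index
    position, then to the lowest position.
    """
    index_col = reference.column(index)  # raises LookupError_ if absent
    keys = reference.keys()
    cand = set(candidates) if candidates is not None else None

    best: tuple[float, int, int, VariantKey] | None = None
    for j, key in enumerate(keys):
        if cand is not None and key not in cand:
            continue
        col = reference.values[:, j]
        if col.std() == 0 or index_col.std() == 0:
            continue
        r2 = float(np.corrcoef(index_col, col)[0, 1] ** 2)
        rank = (-r2, abs(key.pos - index.pos), key.pos)
        if best is None or rank < (best[0], best[1], best[2]):
            best = (*rank, key)
    if best is None or -best[0] <= r2_min:
        return TagSnpChoice(index_snp=index, chosen=None, r2=(-best[0] if best else 0.0))
    return TagSnpChoice(index_snp=index, chosen=best[3], r2=-best[0])
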