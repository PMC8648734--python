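"""Cross-tissue association: per-gene expression PCs + Firth likelihood ratio.

Predicted expression is correlated across tissues, so per-tissue tests are
both redundant and individually underpowered for genes with modest but
consistent effects in many tissues.  The cross-tissue test extracts, per
gene, the principal components of its GReX across tissues (components
sufficient to explain > 80% of variance), adds them jointly to the
covariate model, and compares full vs reduced Firth fits:

    L = 2 (ln L_full - ln L_reduced),   L ~ chi-square(df = #components).

The reduced penalized likelihood is the profile one — the component
coefficients are fixed at zero under the full design's Jeffreys penalty —
so the log-determinant terms of the two fits cancel and L is chi-square
calibrated under the null.

Two scopes mirror common practice: ``all`` tissues (eligibility: models in
>= 5 tissues) and ``brain`` tissues only (>= 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import InvalidInputError
from .firth import fit_firth
from .grex import GReXMatrix
from .simulate import BRAIN_PREFIX

__all__ = [
    "CrossTissueResult",
    "eligible_genes",
    "gene_expression_pcs",
    "cross_tissue_lrt",
    "cross_tissue_scan",
]

_DEFAULT_MIN_TISSUES = {"all": 5, "brain": 3}


@dataclass
class CrossTissueResult:
    gene: str
    scope: str
    n_tissues: int
    n_pcs: int
    L: float
    p: float
    converged: bool = True


def _is_brain(tissue: str) -> bool:
    return tissue.startswith(BRAIN_PREFIX)


def eligible_genes(
    grex: GReXMatrix,
    scope: str = "all",
    min_tissues: int | None = None,
) -> list[str]:
    """Genes with enough modeled tissues in scope (>= 5 all, >= 3 brain)."""
    if scope not in ("all", "brain"):
        raise InvalidInputError(f"unknown scope {scope!r}")
    if min_tissues is None:
        min_tissues = _DEFAULT_MIN_TISSUES[scope]
    counts: dict[str, int] = {}
    for gene, tissue in grex.values.columns:
        if scope == "brain" and not _is_brain(tissue):
            continue
        counts[gene] = counts.get(gene, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_tissues)


def gene_expression_pcs(
    columns: pd.DataFrame | np.ndarray,
    var_threshold: float = 0.8,
) -> tuple[np.ndarray, int, np.ndarray]:
    """PCs of one gene's GReX across tissues.

    Columns are centered and unit-scaled (correlation-matrix PCA) so the
    >80%-variance rule is scale-free; constant columns are dropped with a
    warning.  Returns (scores for the retained components, n_pcs, explained
    variance fractions for all components).  Each component is oriented so
    its largest-magnitude loading is positive.
    """
    M = np.asarray(columns, dtype=float)
    if M.ndim != 2:
        raise InvalidInputError("expected a 2-D tissue-column matrix")
    sd = M.std(axis=0)
    if (sd == 0).any():
        warnings.warn("constant tissue column dropped before PCA", stacklevel=2)
        M = M[:, sd > 0]
        sd = sd[sd > 0]
    if M.shape[1] < 2:
        raise InvalidInputError("need >= 2 non-constant tissue columns for PCA")
    Z = (M - M.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    evar = S**2 / np.sum(S**2)
    n_pcs = int(np.searchsorted(np.cumsum(evar), var_threshold) + 1)
    n_pcs = min(n_pcs, len(evar))
    # sign convention: largest-|loading| positive per component
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = U[:, :n_pcs] * S[:n_pcs] * flip[:n_pcs]
    return scores, n_pcs, evar


def cross_tissue_lrt(
    pc_scores: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    gene: str = "",
    scope: str = "all",
    n_tissues: int = 0,
    covariate_cols: list[str] | None = None,
) -> CrossTissueResult:
    """Firth full-vs-reduced likelihood ratio test for one gene's PC scores."""
    scores = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if scores.shape[0] == 1 and len(phenotype) > 1:
        scores = scores.T
    if scores.shape[1] == 0:
        raise InvalidInputError("no expression PCs supplied; LRT undefined")
    y = np.asarray(phenotype, dtype=float)
    from .assoc import _base_design

    base = _base_design(covariates, covariate_cols)
    X = np.column_stack([base, scores])
    k = scores.shape[1]
    pc_idx = tuple(range(base.shape[1], base.shape[1] + k))
    full = fit_firth(X, y)
    reduced = fit_firth(X, y, fixed_zero=pc_idx)
    if not (full.converged and reduced.converged):
        return CrossTissueResult(
            gene=gene, scope=scope, n_tissues=n_tissues, n_pcs=k,
            L=float("nan"), p=float("nan"), converged=False,
        )
    L = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return CrossTissueResult(
        gene=gene, scope=scope, n_tissues=n_tissues, n_pcs=k,
        L=L, p=float(chi2.sf(L, df=k)),
    )


def cross_tissue_scan(
    grex: GReXMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    scope: str = "all",
    min_tissues: int | None = None,
    var_threshold: float = 0.8,
    covariate_cols: list[str] | None = None,
    study: str = "study_0",
) -> pd.DataFrame:
    """Cross-tissue LRT over every eligible gene; one row per gene."""
    y = np.asarray(phenotype, dtype=float)
    rows = []
    for gene in eligible_genes(grex, scope=scope, min_tissues=min_tissues):
        cols = [
            (g, t)
            for g, t in grex.values.columns
            if g == gene and (scope == "all" or _is_brain(t))
        ]
        block = grex.values[cols].to_numpy(dtype=float)
        nonconst = block.std(axis=0) > 0
        if nonconst.sum() < 2:
            continue
        scores, n_pcs, _ = gene_expression_pcs(
            block[:, nonconst], var_threshold=var_threshold
        )
        res = cross_tissue_lrt(
            scores, y, covariates,
            gene=gene, scope=scope, n_tissues=int(nonconst.sum()),
            covariate_cols=covariate_cols,
        )
        rows.append(
            {
                "GENE": res.gene, "SCOPE": res.scope, "STUDY": study,
                "N_TISSUES": res.n_tissues, "N_PCS": res.n_pcs,
                "L": res.L, "P": res.p, "CONVERGED": res.converged,
                "N": len(y),
            }
        )
    return pd.DataFrame(rows)
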