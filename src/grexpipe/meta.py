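"""Sample-size-weighted meta-analysis, FDR control, and novelty annotation.

Per-study signed gene-level z-scores are combined with the sample-size
weighting scheme of METAL:

    Z_combined = sum_i sqrt(N_i) z_i / sqrt(sum_i N_i),

which is standard normal under the null.  An alternative weighting,
Z = sum_i N_i z_i / sqrt(sum_i N_i^2), is available behind
``weighting='n'``; the sqrt-N scheme is the default because it is the one
consortium meta-analyses actually compute.  Multiple testing across the
pooled family of single- and cross-tissue tests is controlled with the
Benjamini-Hochberg step-up procedure, and significant genes are annotated
as known-region or novel relative to a table of established risk SNPs
(within +/- 10 Mb on the same chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidInputError

__all__ = [
    "MetaResult",
    "combine_z",
    "z_to_p",
    "bh_adjust",
    "annotate_known_loci",
    "meta_analyze",
]

KNOWN_WINDOW_BP = 10_000_000


@dataclass
class MetaResult:
    z: float
    p: float
    n_total: int
    n_studies: int


def combine_z(
    studies: list[tuple[float, float]] | pd.DataFrame,
    weighting: str = "sqrtn",
) -> MetaResult:
    """Combine per-study (z_i, N_i) into a single signed Z and two-sided p.

    ``studies`` is a list of (z, N) pairs or a DataFrame with columns Z and
    N.  Duplicated studies are NOT collapsed — supplying one twice changes
    the result.
    """
    if isinstance(studies, pd.DataFrame):
        pairs = list(zip(studies["Z"].astype(float), studies["N"].astype(float)))
    else:
        pairs = [(float(z), float(n)) for z, n in studies]
    if not pairs:
        raise InvalidInputError("need >= 1 study")
    z = np.array([p[0] for p in pairs])
    n = np.array([p[1] for p in pairs])
    if np.any(n <= 0):
        raise InvalidInputError("all study sample sizes must be positive")
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("per-study z must be finite")
    if weighting == "sqrtn":
        Z = float(np.sum(np.sqrt(n) * z) / np.sqrt(n.sum()))
    elif weighting == "n":
        Z = float(np.sum(n * z) / np.sqrt(np.sum(n**2)))
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    return MetaResult(z=Z, p=z_to_p(Z), n_total=int(n.sum()), n_studies=len(pairs))


def z_to_p(z: float) -> float:
    """Two-sided normal p-value, p = 2 Phi(-|z|)."""
    if not np.isfinite(z):
        raise InvalidInputError("z must be finite")
    return float(min(2.0 * norm.sf(abs(z)), 1.0))


def bh_adjust(pvals, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment over one pooled test family.

    adj_(i) = min_{j >= i} min(1, m p_(j) / j) over the ascending order
    statistics; ties keep their input order.  Returns a table with raw p,
    adjusted p, and the significance flag at ``q``; the family size is
    every p-value supplied.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return pd.DataFrame(
        {"p": p, "p_adj": p_adj, "significant": p_adj <= q, "m": m}
    )


def _norm_chrom(c) -> str:
    s = str(c).lower()
    return s[3:] if s.startswith("chr") else s


def annotate_known_loci(
    gene_positions: pd.DataFrame,
    known_snps: pd.DataFrame,
    window: int = KNOWN_WINDOW_BP,
) -> pd.DataFrame:
    """Flag genes within +/- window of any known risk SNP on the same chromosome.

    ``gene_positions``: columns gene, chrom, pos (transcription start,
    1-based).  ``known_snps``: columns snp, chrom, pos.  Chromosome labels
    are normalized ('chr1' == '1') before comparison.  A gene exactly
    ``window`` bp away is still known-region; one bp further is novel.
    """
    for col in ("gene", "chrom", "pos"):
        if col not in gene_positions.columns:
            raise InvalidInputError(f"gene_positions lacks column {col}")
    for col in ("snp", "chrom", "pos"):
        if col not in known_snps.columns:
            raise InvalidInputError(f"known_snps lacks column {col}")
    ks = known_snps.assign(_c=known_snps["chrom"].map(_norm_chrom))
    rows = []
    for g in gene_positions.itertuples(index=False):
        gc = _norm_chrom(g.chrom)
        same = ks[ks["_c"] == gc]
        if same.empty:
            rows.append((g.gene, None, np.inf, False))
            continue
        dist = (same["pos"].astype(int) - int(g.pos)).abs()
        i = dist.idxmin()
        d = int(dist.loc[i])
        rows.append((g.gene, str(same.loc[i, "snp"]), d, d <= window))
    return pd.DataFrame(
        rows, columns=["gene", "nearest_known_snp", "distance", "within_window"]
    )


def meta_analyze(
    assoc: pd.DataFrame,
    weighting: str = "sqrtn",
    q: float = 0.05,
    keys: tuple[str, ...] = ("GENE", "TISSUE"),
) -> pd.DataFrame:
    """Meta-analyze per-study association rows and apply BH over the result.

    ``assoc`` rows carry per-study Z and N keyed by ``keys`` (gene x tissue
    for single-tissue results, gene x scope for cross-tissue).  Single- and
    cross-tissue tables may be concatenated first so the FDR family is
    pooled, per standard study-wide correction.
    """
    rows = []
    for key, sub in assoc.groupby(list(keys), sort=True):
        res = combine_z(sub[["Z", "N"]], weighting=weighting)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(
            Z=res.z, P=res.p, N=res.n_total, N_STUDIES=res.n_studies
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    fdr = bh_adjust(out["P"].to_numpy(), q=q)
    out["P_ADJ"] = fdr["p_adj"].to_numpy()
    out["SIGNIFICANT"] = fdr["significant"].to_numpy()
    return out
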