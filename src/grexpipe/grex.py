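"""Imputation of genetically regulated expression (GReX).

A tissue-specific weight model maps cis variants (with an explicit effect
allele) to linear weights; predicted expression for individual i is

    GReX_ig = sum_k w_kg * d'_ik,

where d' is the alt-allele dosage, flipped to 2 - d when the model's effect
allele is the reference allele.  Model variants absent from the dosage set
contribute zero (the PrediXcan convention); per-model coverage is reported so
low-coverage genes can be filtered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidInputError

__all__ = [
    "VariantKey",
    "DosageMatrix",
    "WeightModel",
    "GReXMatrix",
    "HarmonizationReport",
    "filter_variants",
    "harmonize",
    "impute_grex",
]


class VariantKey(NamedTuple):
    """Positional identity of a biallelic variant (1-based coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str


#: columns every variant-metadata table must carry
_META_COLS = ("chrom", "pos", "ref", "alt", "rsid", "maf", "r2")


@dataclass
class DosageMatrix:
    """Individuals x variants alt-allele dosage matrix with metadata.

    ``values`` lies in [0, 2]; ``variant_meta`` has one row per column with
    chrom/pos/ref/alt/rsid plus the per-variant MAF and imputation quality R²
    the upstream QC filters act on.
    """

    values: np.ndarray
    variant_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variant_meta)):
            raise InvalidInputError("dosage shape does not match metadata")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            raise InvalidInputError("dosages must lie in [0, 2]")
        missing = set(_META_COLS) - set(self.variant_meta.columns)
        if missing:
            raise InvalidInputError(f"variant_meta lacks columns {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_meta)

    def keys(self) -> list[VariantKey]:
        m = self.variant_meta
        return [
            VariantKey(str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(m["chrom"], m["pos"], m["ref"], m["alt"])
        ]

    def column(self, key: VariantKey) -> np.ndarray:
        """Dosage column for one variant (positional identity)."""
        m = self.variant_meta
        hit = (
            (m["chrom"].astype(str) == key.chrom)
            & (m["pos"] == key.pos)
            & (m["ref"] == key.ref)
            & (m["alt"] == key.alt)
        )
        idx = np.flatnonzero(hit.to_numpy())
        if idx.size == 0:
            from .errors import LookupError_

            raise LookupError_(f"variant {key} absent from dosage set")
        return self.values[:, idx[0]]


@dataclass
class WeightModel:
    """Sparse per-gene, per-tissue expression prediction model.

    ``entries`` columns: rsid, chrom, pos, ref, alt, effect_allele, weight.
    """

    gene: str
    tissue: str
    gene_chrom: str
    gene_tss: int
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"rsid", "chrom", "pos", "ref", "alt", "effect_allele", "weight"}
        missing = need - set(self.entries.columns)
        if missing:
            raise InvalidInputError(f"model entries lack columns {sorted(missing)}")
        dup = self.entries.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if dup.any():
            raise InvalidInputError(
                f"duplicate variant in model {self.gene}@{self.tissue}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def scaled(self, a: float) -> "WeightModel":
        e = self.entries.copy()
        e["weight"] = e["weight"] * a
        return WeightModel(self.gene, self.tissue, self.gene_chrom, self.gene_tss, e)


@dataclass
class HarmonizationReport:
    """Per-entry allele-matching status for one model against one dosage set.

    Statuses partition the model entries: ``matched`` (effect allele is alt),
    ``flipped`` (effect allele is ref; dosage used as 2 - d), ``missing``
    (variant absent), ``allele_mismatch`` (position found, alleles
    irreconcilable).
    """

    statuses: pd.Series
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.statuses.value_counts().to_dict()


@dataclass
class GReXMatrix:
    """Predicted expression, individuals x (gene, tissue).

    ``values`` has a (gene, tissue) column MultiIndex; ``coverage`` records
    (n_snps_used, n_snps_in_model) per column.  Columns with zero matched
    model SNPs are omitted.
    """

    values: pd.DataFrame
    coverage: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.values.columns})

    def tissues_for(self, gene: str) -> list[str]:
        return [t for g, t in self.values.columns if g == gene]

    def gene_block(self, gene: str) -> pd.DataFrame:
        cols = [c for c in self.values.columns if c[0] == gene]
        return self.values[cols]


def filter_variants(
    dosage: DosageMatrix, maf_min: float = 0.05, r2_min: float = 0.5
) -> DosageMatrix:
    """Apply the upstream QC filter: keep MAF > maf_min AND R² > r2_min.

    Both inequalities are strict.  Raises ``EmptyResultError`` when nothing
    survives.
    """
    if not (0 <= maf_min <= 0.5):
        raise InvalidInputError("maf_min must lie in [0, 0.5]")
    if not (0 <= r2_min <= 1):
        raise InvalidInputError("r2_min must lie in [0, 1]")
    m = dosage.variant_meta
    keep = (m["maf"].to_numpy() > maf_min) & (m["r2"].to_numpy() > r2_min)
    if not keep.any():
        raise EmptyResultError(
            f"no variants pass MAF > {maf_min} and R² > {r2_min}"
        )
    return DosageMatrix(
        values=dosage.values[:, keep],
        variant_meta=m.loc[keep].reset_index(drop=True),
        sample_ids=dosage.sample_ids,
    )


def _meta_index(variant_meta: pd.DataFrame):
    """(chrom,pos) -> list of (row, ref, alt); rsid -> row fallback."""
    by_pos: dict[tuple[str, int], list[tuple[int, str, str]]] = {}
    by_rsid: dict[str, int] = {}
    for i, row in enumerate(variant_meta.itertuples(index=False)):
        by_pos.setdefault((str(row.chrom), int(row.pos)), []).append(
            (i, str(row.ref), str(row.alt))
        )
        by_rsid[str(row.rsid)] = i
    return by_pos, by_rsid


def harmonize(
    model: WeightModel, variant_meta: pd.DataFrame
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align a weight model's entries with a dosage set's variants.

    Matching prefers positional identity (chrom, pos, unordered allele pair);
    rsid is the fallback key.  Returns an aligned table with columns
    ``col`` (dosage column index), ``weight``, ``flip`` (effect allele is the
    dosage ref allele) restricted to usable entries, plus a report covering
    every entry.
    """
    by_pos, by_rsid = _meta_index(variant_meta)
    statuses = []
    rows = []
    for e in model.entries.itertuples(index=False):
        candidates = by_pos.get((str(e.chrom), int(e.pos)), [])
        hit = None
        for i, ref, alt in candidates:
            if {ref, alt} == {str(e.ref), str(e.alt)}:
                hit = (i, ref, alt)
                break
        if hit is None and candidates:
            statuses.append("allele_mismatch")
            continue
        if hit is None:
            j = by_rsid.get(str(e.rsid))
            if j is not None:
                ref = str(variant_meta["ref"].iloc[j])
                alt = str(variant_meta["alt"].iloc[j])
                if {ref, alt} == {str(e.ref), str(e.alt)}:
                    hit = (j, ref, alt)
                else:
                    statuses.append("allele_mismatch")
                    continue
        if hit is None:
            statuses.append("missing")
            continue
        i, ref, alt = hit
        ea = str(e.effect_allele)
        if ea == alt:
            statuses.append("matched")
            rows.append((i, float(e.weight), False))
        elif ea == ref:
            statuses.append("flipped")
            rows.append((i, float(e.weight), True))
        else:
            statuses.append("allele_mismatch")
    aligned = pd.DataFrame(rows, columns=["col", "weight", "flip"])
    report = HarmonizationReport(statuses=pd.Series(statuses, dtype="object"))
    return aligned, report


def impute_grex(
    dosage: DosageMatrix, models: Iterable[WeightModel]
) -> GReXMatrix:
    """Predict expression for every model with >= 1 matched variant."""
    import warnings

    cols = {}
    cov_rows = []
    D = dosage.values
    for model in models:
        aligned, _ = harmonize(model, dosage.variant_meta)
        used = len(aligned)
        cov_rows.append((model.gene, model.tissue, used, model.n_snps))
        if used == 0:
            if model.n_snps > 0:
                warnings.warn(
                    f"model {model.gene}@{model.tissue}: no variant matched; "
                    "column omitted",
                    stacklevel=2,
                )
            continue
        w = aligned["weight"].to_numpy()
        sign = np.where(aligned["flip"].to_numpy(), -1.0, 1.0)
        offset = 2.0 * float(w[aligned["flip"].to_numpy()].sum())
        g = D[:, aligned["col"].to_numpy()] @ (w * sign) + offset
        cols[(model.gene, model.tissue)] = g
    values = pd.DataFrame(cols, index=pd.Index(dosage.sample_ids, name="IID"))
    if len(values.columns):
        values.columns = pd.MultiIndex.from_tuples(
            values.columns, names=["gene", "tissue"]
        )
    coverage = pd.DataFrame(
        cov_rows, columns=["gene", "tissue", "n_snps_used", "n_snps_in_model"]
    )
    return GReXMatrix(values=values, coverage=coverage)
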