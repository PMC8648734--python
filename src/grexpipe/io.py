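"""Readers and writers for the pipeline's on-disk formats.

Dosages travel as VCF v4.2 with a DS FORMAT field (read back through
cyvcf2, falling back to GT when DS is absent) or as a plain TSV matrix.
Weight models are stored both as a single-file relational database with the
PrediXcan schema (tables ``weights`` and ``extra``) and as an equivalent
TSV.  Phenotypes/covariates, GWAS summary statistics, the GReX matrix, and
the per-gene LD covariance all travel as TSV.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .grex import DosageMatrix, GReXMatrix, WeightModel
from .summary import LDReference

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_weights_db",
    "read_weights_db",
    "write_weights_tsv",
    "read_weights_tsv",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_covariance_tsv",
    "read_covariance_tsv",
    "write_grex_tsv",
]


def write_vcf(dosage: DosageMatrix, path: str | Path) -> Path:
    """Write dosages as VCF v4.2, one record per variant, DS per sample.

    INFO carries AF (alt frequency) and R2 (simulated imputation quality) so
    a round-trip preserves the fields the QC filters need.
    """
    path = Path(path)
    m = dosage.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosage.sample_ids)
            + "\n"
        )
        for j in range(dosage.n_variants):
            af = dosage.values[:, j].mean() / 2.0
            fields = [
                str(m["chrom"].iloc[j]),
                str(int(m["pos"].iloc[j])),
                str(m["rsid"].iloc[j]),
                str(m["ref"].iloc[j]),
                str(m["alt"].iloc[j]),
                ".",
                "PASS",
                f"AF={af:.6g};R2={m['r2'].iloc[j]:.6g}",
                "DS",
            ]
            fields += [f"{d:.4g}" for d in dosage.values[:, j]]
            fh.write("\t".join(fields) + "\n")
    return path


def read_vcf(path: str | Path) -> DosageMatrix:
    """Read a VCF with DS dosages (GT fallback) into a DosageMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        if rec.format("DS") is not None:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:  # GT fallback: count alt alleles
            gt = np.asarray(rec.genotype.array())[:, :2]
            ds = np.clip(gt, 0, 1).sum(axis=1).astype(float)
        af = ds.mean() / 2.0
        r2 = rec.INFO.get("R2", 1.0)
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                rec.REF,
                rec.ALT[0],
                rec.ID or f"{rec.CHROM}:{rec.POS}",
                min(af, 1 - af),
                float(r2),
            )
        )
        cols.append(ds)
    meta = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "rsid", "maf", "r2"]
    )
    return DosageMatrix(
        values=np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        variant_meta=meta,
        sample_ids=samples,
    )


def write_phenotype_tsv(
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    sample_ids: list[str],
    path: str | Path,
) -> Path:
    path = Path(path)
    out = pd.DataFrame({"IID": sample_ids, "STATUS": np.asarray(phenotype, int)})
    out = pd.concat([out, covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_phenotype_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t")
    for col in ("IID", "STATUS", "SEX", "AGE"):
        if col not in df.columns:
            raise InvalidInputError(f"phenotype table lacks column {col}")
    covars = df.drop(columns=["IID", "STATUS"])
    return df["STATUS"].to_numpy(int), covars, df["IID"].astype(str).tolist()


_WEIGHT_COLS = ["rsid", "gene", "weight", "ref_allele", "eff_allele"]


def write_weights_db(models: list[WeightModel], path: str | Path) -> Path:
    """Single-file relational database with the PrediXcan schema, one per tissue.

    Table ``weights``(rsid, gene, weight, ref_allele, eff_allele) and table
    ``extra``(gene, genename, n_snps_in_model).  Multiple tissues go to
    sibling files suffixed with the tissue label.
    """
    path = Path(path)
    tissues = sorted({m.tissue for m in models})
    if len(tissues) > 1:
        for t in tissues:
            write_weights_db(
                [m for m in models if m.tissue == t],
                path.with_name(f"{path.stem}_{t}{path.suffix}"),
            )
        return path
    con = sqlite3.connect(path)
    try:
        con.execute("DROP TABLE IF EXISTS weights")
        con.execute("DROP TABLE IF EXISTS extra")
        con.execute(
            "CREATE TABLE weights (rsid TEXT, gene TEXT, weight REAL,"
            " ref_allele TEXT, eff_allele TEXT)"
        )
        con.execute(
            "CREATE TABLE extra (gene TEXT, genename TEXT, n_snps_in_model INT)"
        )
        for m in models:
            for e in m.entries.itertuples(index=False):
                other = e.ref if str(e.effect_allele) == str(e.alt) else e.alt
                con.execute(
                    "INSERT INTO weights VALUES (?,?,?,?,?)",
                    (str(e.rsid), m.gene, float(e.weight), str(other), str(e.effect_allele)),
                )
            con.execute(
                "INSERT INTO extra VALUES (?,?,?)", (m.gene, m.gene, m.n_snps)
            )
        con.commit()
    finally:
        con.close()
    return path


def read_weights_db(
    path: str | Path, tissue: str, variant_table: pd.DataFrame
) -> list[WeightModel]:
    """Load PrediXcan-schema weights, resolving variant keys through rsid."""
    con = sqlite3.connect(path)
    try:
        w = pd.read_sql_query("SELECT * FROM weights", con)
    finally:
        con.close()
    return _models_from_flat(w, tissue, variant_table)


def write_weights_tsv(models: list[WeightModel], path: str | Path) -> Path:
    rows = []
    for m in models:
        for e in m.entries.itertuples(index=False):
            rows.append(
                (m.gene, m.tissue, str(e.rsid), str(e.effect_allele), float(e.weight))
            )
    pd.DataFrame(
        rows, columns=["gene", "tissue", "variant", "effect_allele", "weight"]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_weights_tsv(
    path: str | Path, variant_table: pd.DataFrame, tissue: str | None = None
) -> list[WeightModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for (gene, tis), sub in df.groupby(["gene", "tissue"]):
        if tissue is not None and tis != tissue:
            continue
        flat = sub.rename(columns={"variant": "rsid", "effect_allele": "eff_allele"})
        models.extend(_models_from_flat(flat.assign(gene=gene), tis, variant_table))
    return models


def _models_from_flat(
    flat: pd.DataFrame, tissue: str, variant_table: pd.DataFrame
) -> list[WeightModel]:
    vt = variant_table.set_index("rsid")
    models = []
    for gene, sub in flat.groupby("gene"):
        rows = []
        tss, chrom = None, None
        for e in sub.itertuples(index=False):
            rsid = str(e.rsid)
            if rsid not in vt.index:
                continue
            v = vt.loc[rsid]
            if tss is None:
                tss, chrom = int(v["pos"]), str(v["chrom"])
            rows.append(
                (
                    rsid, str(v["chrom"]), int(v["pos"]), str(v["ref"]),
                    str(v["alt"]), str(e.eff_allele), float(e.weight),
                )
            )
        entries = pd.DataFrame(
            rows,
            columns=["rsid", "chrom", "pos", "ref", "alt", "effect_allele", "weight"],
        )
        models.append(
            WeightModel(
                gene=str(gene), tissue=tissue,
                gene_chrom=chrom or "1", gene_tss=tss or 0, entries=entries,
            )
        )
    return models


def write_summary_tsv(stats: pd.DataFrame, path: str | Path) -> Path:
    stats.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"SNP", "A1", "A2", "Z", "N"}
    if need - set(df.columns):
        raise InvalidInputError(f"summary table lacks {sorted(need - set(df.columns))}")
    return df


def write_covariance_tsv(ld: LDReference, path: str | Path) -> Path:
    """Covariance TSV: GENE, RSID1, RSID2, VALUE (upper triangle incl. diagonal)."""
    rows = []
    for gene in ld.genes():
        rsids, gamma = ld.gene(gene)
        for i in range(len(rsids)):
            for j in range(i, len(rsids)):
                rows.append((gene, rsids[i], rsids[j], gamma[i, j]))
    pd.DataFrame(rows, columns=["GENE", "RSID1", "RSID2", "VALUE"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_covariance_tsv(path: str | Path) -> LDReference:
    df = pd.read_csv(path, sep="\t")
    covs = {}
    for gene, sub in df.groupby("GENE"):
        rsids = sorted(set(sub["RSID1"]) | set(sub["RSID2"]))
        pos = {r: i for i, r in enumerate(rsids)}
        gamma = np.zeros((len(rsids), len(rsids)))
        for e in sub.itertuples(index=False):
            i, j = pos[e.RSID1], pos[e.RSID2]
            gamma[i, j] = gamma[j, i] = float(e.VALUE)
        covs[str(gene)] = (rsids, gamma)
    return LDReference(covs)


def write_grex_tsv(grex: GReXMatrix, path: str | Path) -> Path:
    """GReX matrix TSV: rows = individuals, columns = GENE@TISSUE."""
    flat = grex.values.copy()
    flat.columns = [f"{g}@{t}" for g, t in flat.columns]
    flat.to_csv(path, sep="\t")
    return Path(path)
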