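#!/usr/bin/env python
"""Meta-analyze across studies, control FDR, and annotate novelty.

Combines per-study z-scores with the sqrt(N) sample-size weighting,
pools single- and cross-tissue tests into one Benjamini-Hochberg family,
and flags significant genes as known-region or novel relative to a list
of established risk SNPs (+/- 10 Mb).
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import grexpipe as gp
from grexpipe import io

warnings.filterwarnings("ignore")

BASE = Path(__file__).resolve().parent.parent / "results"
ASSOC = BASE / "assoc"
OUT = BASE / "meta"
OUT.mkdir(parents=True, exist_ok=True)

single = pd.read_csv(ASSOC / "single_tissue.tsv", sep="\t")
cross = pd.read_csv(ASSOC / "cross_tissue.tsv", sep="\t")

meta_single = gp.meta_analyze(single, keys=("GENE", "TISSUE"))

# cross-tissue LRT p-values are one-sided chi-square: convert to an
# equivalent |z| for the same weighting scheme, carrying no direction
cross = cross.dropna(subset=["P"]).copy()
from scipy.stats import norm

cross["Z"] = norm.isf(cross["P"] / 2)
meta_cross = gp.meta_analyze(cross, keys=("GENE", "SCOPE"))

# one pooled FDR family across single- and cross-tissue tests
pooled_p = np.r_[meta_single["P"].to_numpy(), meta_cross["P"].to_numpy()]
fdr = gp.bh_adjust(pooled_p)
meta_single["P_ADJ"] = fdr["p_adj"].to_numpy()[: len(meta_single)]
meta_single["SIGNIFICANT"] = fdr["significant"].to_numpy()[: len(meta_single)]
meta_cross["P_ADJ"] = fdr["p_adj"].to_numpy()[len(meta_single):]
meta_cross["SIGNIFICANT"] = fdr["significant"].to_numpy()[len(meta_single):]

# novelty relative to two synthetic "known risk SNPs"
cfg = gp.SimulationConfig(seed=2024)
vt = gp.simulate_variant_table(cfg)
models = io.read_weights_tsv(BASE / "cohorts" / "weight_models.tsv", vt)
gene_pos = pd.DataFrame(
    [
        {"gene": m.gene, "chrom": m.gene_chrom, "pos": m.gene_tss}
        for m in models
    ]
).drop_duplicates("gene")
known = pd.DataFrame(
    {
        "snp": ["rs_known_1", "rs_known_2"],
        "chrom": ["1", "1"],
        "pos": [int(vt["pos"].iloc[10]), int(vt["pos"].iloc[180])],
    }
)
novelty = gp.annotate_known_loci(gene_pos, known, window=100_000)
meta_single = meta_single.merge(
    novelty.rename(columns={"gene": "GENE"}), on="GENE", how="left"
)
meta_single["NOVEL"] = ~meta_single["within_window"].fillna(True)

meta_single.to_csv(OUT / "meta_single_tissue.tsv", sep="\t", index=False)
meta_cross.to_csv(OUT / "meta_cross_tissue.tsv", sep="\t", index=False)

sig = meta_single[meta_single["SIGNIFICANT"]]
print(
    f"{len(meta_single)} single-tissue + {len(meta_cross)} cross-tissue "
    f"meta tests; {sig['GENE'].nunique()} significant genes "
    f"({int(sig['NOVEL'].sum())} signals outside known windows)"
)
print(
    sig.sort_values("P")[["GENE", "TISSUE", "Z", "P", "P_ADJ", "NOVEL"]]
    .head(10)
    .to_string(index=False)
)
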