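#!/usr/bin/env python
"""Single-tissue Firth association within each study.

Tests every gene x tissue GReX column against case-control status with
Firth-penalized logistic regression (profile penalized-likelihood-ratio
p-values), adjusting for sex, age, and genetic PCs.
"""

import warnings
from pathlib import Path

import pandas as pd

import grexpipe as gp
from grexpipe import io

warnings.filterwarnings("ignore")

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "assoc"
OUT.mkdir(parents=True, exist_ok=True)

cfg = gp.SimulationConfig(seed=2024)
variant_table = gp.simulate_variant_table(cfg)
models = io.read_weights_tsv(BASE / "cohorts" / "weight_models.tsv", variant_table)

tables = []
for vcf in sorted((BASE / "cohorts").glob("study_*.vcf")):
    study = vcf.stem
    dosages = gp.filter_variants(io.read_vcf(vcf), maf_min=0.05, r2_min=0.5)
    y, covars, _ = io.read_phenotype_tsv(BASE / "cohorts" / f"{study}.pheno.tsv")
    grex = gp.impute_grex(dosages, models)
    res = gp.assoc_single_tissue(grex, y, covars, study=study)
    tables.append(res)
    top = res.loc[res["P"].idxmin()]
    print(
        f"{study}: {len(res)} tests; top hit {top['GENE']}@{top['TISSUE']} "
        f"z={top['Z']:.2f} p={top['P']:.2e}"
    )

pd.concat(tables).to_csv(OUT / "single_tissue.tsv", sep="\t", index=False)
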