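#!/usr/bin/env python
"""Cross-tissue likelihood-ratio tests within each study.

Per eligible gene: principal components of its GReX across tissues
(retained to >80% variance), Firth full-vs-reduced fits, chi-square with
df = number of components.  Runs both scopes — all tissues (>= 5 models)
and brain tissues (>= 3).
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
    for scope in ("all", "brain"):
        res = gp.cross_tissue_scan(grex, y, covars, scope=scope, study=study)
        tables.append(res)
        if not res.empty:
            top = res.loc[res["P"].idxmin()]
            print(
                f"{study} [{scope}]: {len(res)} genes; top {top['GENE']} "
                f"L={top['L']:.1f} df={top['N_PCS']} p={top['P']:.2e}"
            )

pd.concat(tables).to_csv(OUT / "cross_tissue.tsv", sep="\t", index=False)
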