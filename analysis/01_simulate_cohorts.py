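#!/usr/bin/env python
"""Simulate the multi-study synthetic experiment and write its artifacts.

Generates three case-control studies of unequal size and imbalance on a
shared variant map, with sparse cross-tissue eQTL weight models and a
known causal-gene truth, then writes the on-disk formats every later stage
reads: VCF dosages, phenotype/covariate TSVs, weight models (relational
database + TSV), and the truth record.
"""

import json
import warnings
from pathlib import Path

import grexpipe as gp
from grexpipe import io

warnings.filterwarnings("ignore")

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)

cfg = gp.SimulationConfig(seed=2024)
cohorts, models, truth = gp.simulate_study_set(cfg)

for cohort in cohorts:
    io.write_vcf(cohort.dosages, OUT / f"{cohort.study_id}.vcf")
    io.write_phenotype_tsv(
        cohort.phenotype, cohort.covariates, cohort.dosages.sample_ids,
        OUT / f"{cohort.study_id}.pheno.tsv",
    )
    print(
        f"{cohort.study_id}: n={cohort.dosages.n_samples} "
        f"cases={cohort.n_cases} variants={cohort.dosages.n_variants}"
    )

io.write_weights_tsv(models, OUT / "weight_models.tsv")
io.write_weights_db(models, OUT / "weight_models.db")

with open(OUT / "truth.json", "w") as fh:
    json.dump(
        {
            "causal_genes": sorted(truth.causal_genes),
            "liability_effects": truth.liability_effects,
            "causal_tissue": truth.causal_tissue,
        },
        fh,
        indent=2,
    )
print(
    f"truth: {len(truth.causal_genes)} causal genes in {truth.causal_tissue}: "
    f"{ {g: round(b, 3) for g, b in truth.liability_effects.items()} }"
)
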