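"""Shared fixtures: one small simulated multi-study experiment per session."""

import warnings

import numpy as np
import pandas as pd
import pytest

import grexpipe as gp


@pytest.fixture(scope="session")
def default_config():
    return gp.SimulationConfig(seed=202)


@pytest.fixture(scope="session")
def study_set(default_config):
    """Cohorts, weight models, and truth for the default configuration."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gp.simulate_study_set(default_config)


@pytest.fixture(scope="session")
def first_cohort(study_set):
    cohorts, _, _ = study_set
    return cohorts[0]


@pytest.fixture()
def toy_dosage():
    """Hand-written 4-individual x 3-variant dosage matrix."""
    values = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 0.0, 1.0],
            [2.0, 2.0, 0.0],
            [1.0, 1.0, 1.0],
        ]
    )
    meta = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [100, 200, 300],
            "ref": ["A", "A", "T"],
            "alt": ["G", "C", "C"],
            "rsid": ["rs1", "rs2", "rs3"],
            "maf": [0.3, 0.4, 0.25],
            "r2": [0.9, 0.8, 0.95],
        }
    )
    return gp.DosageMatrix(values=values, variant_meta=meta, sample_ids=list("abcd"))


def toy_model(entries_rows, gene="G1", tissue="brain_00"):
    entries = pd.DataFrame(
        entries_rows,
        columns=["rsid", "chrom", "pos", "ref", "alt", "effect_allele", "weight"],
    )
    return gp.WeightModel(
        gene=gene, tissue=tissue, gene_chrom="1", gene_tss=100, entries=entries
    )
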