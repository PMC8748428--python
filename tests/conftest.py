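"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from equiclock import BetaMatrix, SampleSheet, TransformSpec
from equiclock.synthetic_data import (
    DEFAULT_SPECIES,
    Cohort,
    SimConfig,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default equid aging dataset (blood 188+76+5+7, liver 48, 2000 CpGs)."""
    return simulate_methylation(SimConfig(seed=1))


@pytest.fixture(scope="session")
def blood_subset(default_dataset):
    beta, sheet, annot, truth = default_dataset
    ids = sheet.sample_ids[sheet.tissue == "blood"]
    return beta.subset_samples(ids), sheet.subset(ids), annot, truth


@pytest.fixture(scope="session")
def loglinear_spec():
    return TransformSpec.from_species_table("loglinear", DEFAULT_SPECIES)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast single-tissue horse cohort for clock/pipeline unit tests."""
    cfg = SimConfig(
        n_cpgs=300, n_causal_pos=30, n_causal_neg=30,
        cohorts=(Cohort("blood", "horse", 60, 0.1, 28.0,
                        n_female=30, n_gelding=15),),
        n_castration_cpgs=10, seed=7,
    )
    return simulate_methylation(cfg)


@pytest.fixture()
def single_cpg_dataset():
    """Noiseless y = 10 * beta of one CpG; two other CpGs constant."""
    rng = np.random.default_rng(3)
    n = 30
    driver = rng.uniform(0.05, 0.95, n)
    values = pd.DataFrame(
        {
            "cg_driver": driver,
            "cg_const_a": 0.4,
            "cg_const_b": 0.7,
        },
        index=pd.Index([f"s{i:02d}" for i in range(n)], name="sample_id"),
    )
    beta = BetaMatrix(values)
    sheet = SampleSheet(pd.DataFrame(
        {
            "age": 10.0 * driver,
            "species": "horse",
            "tissue": "blood",
            "sex": "female",
            "castrated": "not_applicable",
        },
        index=values.index,
    ))
    return beta, sheet
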