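"""Shared fixtures: one default synthetic dataset per session plus helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from agingsig.cohorts import assign_cohorts, default_tissue_map
from agingsig.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default-condition synthetic study (500 donors x 2,000 genes)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_assignment(default_dataset):
    donors, samples, _, _, _ = default_dataset
    return assign_cohorts(donors, samples, "subcutaneous_fat", default_tissue_map())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_donor_table(rows: list[dict]) -> pd.DataFrame:
    """Construct a donor table from compact dicts, filling defaults."""
    defaults = {"sex": "female", "bmi": 24.0, "disease_codes": "", "pmi": 500.0}
    out = []
    for i, row in enumerate(rows):
        rec = {"donor_id": f"D{i:03d}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)


def make_sample_table(donors: pd.DataFrame, tissue: str = "subcutaneous_fat") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(len(donors))],
            "donor_id": donors["donor_id"].to_numpy(),
            "tissue": tissue,
            "rin": 7.0,
            "ischemic_time": 300.0,
        }
    )
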