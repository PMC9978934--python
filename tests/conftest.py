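import numpy as np
import pandas as pd
import pytest

import indigoferm as ig
from indigoferm.synthetic_data import BatchSpec, FermentationDesign


@pytest.fixture(scope="session")
def small_design():
    """Two batches, short schedule — fast fixture for module tests."""
    return FermentationDesign(
        batches=(BatchSpec("B1", 25.0, 9.8), BatchSpec("B3", 25.0, 10.7)),
        sampling_days=(1, 2, 3, 4, 5, 6, 7, 10, 16, 29),
        read_depth_range=(10_000, 20_000),
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return ig.simulate_dataset(
        design=small_design,
        taxa=ig.default_taxa(20, seed=11),
        n_kos=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def study_dataset():
    """Full study layout (4 batches, days 1-209) at default conditions."""
    return ig.simulate_dataset(seed=5)


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        {"S1": [50, 30, 15, 5], "S2": [10, 60, 20, 10], "S3": [25, 25, 25, 25]},
        index=["TA", "TB", "TC", "TD"],
    )
    meta = pd.DataFrame(
        {"batch_id": ["B1", "B1", "B1"], "day": [1, 2, 3],
         "ph": [10.5, 10.2, 10.0], "orp": [50.0, -200.0, -400.0]},
        index=["S1", "S2", "S3"],
    )
    return ig.FeatureTable(counts=counts, sample_meta=meta)
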