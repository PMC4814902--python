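import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import drugprior as dp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_selection_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", dp.feature_selection.SelectionWarning)
        warnings.simplefilter("ignore", dp.response_stats.StatsWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset() -> dp.AlignedDataset:
    """A compact synthetic panel shared by read-only tests."""
    cfg = dp.SyntheticConfig(
        n_cells=120,
        n_genes={"mutation": 40, "variation": 40, "expression": 60, "cnv": 50},
        n_drugs=4,
        n_causal=3,
        noise_sd=0.3,
        seed=11,
    )
    return dp.generate_synthetic_dataset(cfg)


@pytest.fixture()
def tiny_response() -> dp.DrugResponseTable:
    """Hand-written 4-cell, 2-drug response table with one missing IC50."""
    ic50 = pd.DataFrame(
        {"A": [0.1, 2.0, 0.5, 8.0], "B": [1.0, np.nan, 0.2, 0.3]},
        index=["c1", "c2", "c3", "c4"],
    )
    tissue = {"c1": "lung", "c2": "lung", "c3": "breast", "c4": "breast"}
    return dp.DrugResponseTable(ic50=ic50, tissue=tissue)


def make_binary_matrix(values, cells, genes, feature_type="mutation"):
    return dp.FeatureMatrix(
        feature_type=feature_type,
        values=pd.DataFrame(values, index=cells, columns=genes, dtype=float),
    )
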