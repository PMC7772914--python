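import numpy as np
import pandas as pd
import pytest

from plato.datasets import FeatureTable, PULabels, PlatoConfig
from plato.synthetic import SyntheticSpec, gen_psm_fixture, gen_pu_tabular


@pytest.fixture
def mixed_table():
    """Six samples × four typed features with a few missing cells."""
    df = pd.DataFrame(
        {
            "depth": [10.0, 20.0, np.nan, 40.0, 15.0, 25.0],
            "vaf": [0.5, 0.1, 0.3, np.nan, 0.2, 0.4],
            "caller": ["snvq", "strelka", "snvq", "both", np.nan, "both"],
            "dbsnp": ["yes", "no", "no", "yes", "no", "no"],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return FeatureTable(df, numeric=["depth", "vaf"], categorical=["caller", "dbsnp"])


@pytest.fixture(scope="session")
def small_pu():
    """Separable PU dataset small enough for fast end-to-end runs."""
    spec = SyntheticSpec(n_positives=40, n_unlabeled=1500, n_hidden_positives=15,
                         class_separation=5.0, missing_rate=0.0, seed=7)
    table, labels, truth = gen_pu_tabular(spec)
    return table, labels, truth


@pytest.fixture(scope="session")
def psm_table():
    """Concatenated-search PSM fixture with known true targets."""
    psms, truth = gen_psm_fixture(n_true_targets=300, n_false_targets=300,
                                  n_decoys=300, score_shift=3.0, seed=5)
    return psms, truth


@pytest.fixture
def rf_config():
    return PlatoConfig(N=3, classifier_mode="random_forest", seed=0)
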