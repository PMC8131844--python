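import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sipdetect as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def taxonomy_from_truth(truth: pd.DataFrame) -> sd.TaxonomyTable:
    return sd.TaxonomyTable(
        truth[["otu_id", "taxonomy"]].rename(columns={"taxonomy": "lineage"})
    )


@pytest.fixture(scope="session")
def default_config() -> sd.GradientConfig:
    return sd.GradientConfig()


@pytest.fixture(scope="session")
def small_experiment(default_config):
    """One simulated acetate-style incubation: 60 OTUs, 10% labeled at afe 0.5."""
    truth = sd.make_community(60, 0.1, seed=101, afe_13C=0.5)
    counts, metadata, truth = sd.simulate_experiment(
        truth, default_config, timepoints=[7], seed=102, treatment="acetate"
    )
    return counts, metadata, truth, taxonomy_from_truth(truth)
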