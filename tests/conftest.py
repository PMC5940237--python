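import numpy as np
import pandas as pd
import pytest

from percnorm import FeatureTable, SampleMetadata


@pytest.fixture
def toy_table():
    """3 features x 4 samples of relative abundances."""
    frame = pd.DataFrame(
        {
            "s1": [0.2, 0.3, 0.5],
            "s2": [0.0, 0.4, 0.6],
            "s3": [0.1, 0.1, 0.8],
            "s4": [0.25, 0.25, 0.5],
        },
        index=["fA", "fB", "fC"],
    )
    return FeatureTable(frame, state="relative")


@pytest.fixture
def toy_metadata():
    return SampleMetadata.from_mappings(
        {"s1": "st1", "s2": "st1", "s3": "st2", "s4": "st2"},
        {"s1": "control", "s2": "case", "s3": "control", "s4": "case"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_table(rng, n_features=6, n_samples=5, sparsity=0.3, state="unknown"):
    values = rng.gamma(1.0, 1.0, size=(n_features, n_samples))
    values[rng.random(values.shape) < sparsity] = 0.0
    frame = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return FeatureTable(frame, state=state)
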