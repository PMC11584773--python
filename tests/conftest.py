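import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from omicshub.matrix import OmicsFeatureMatrix, default_sample_table

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def samples():
    return default_sample_table()


@pytest.fixture
def make_matrix(samples):
    """Build an OmicsFeatureMatrix from a raw array (one layer by default)."""

    def build(values, layer="transcript", layers=None, ids=None):
        values = np.asarray(values, dtype=float)
        n_feat, n_samp = values.shape
        if n_samp == len(samples):
            table = samples
        else:  # one wild-type group with n replicates
            table = pd.DataFrame({
                "sample_id": [f"s{i:02d}" for i in range(n_samp)],
                "genotype": "wildtype",
                "tissue": "green_leaf",
                "replicate": np.arange(1, n_samp + 1),
            })
        if ids is None:
            ids = [f"{layer}:f{i:03d}" for i in range(n_feat)]
        frame = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"),
                             columns=list(table["sample_id"]))
        layer_series = pd.Series(layers if layers is not None else layer,
                                 index=frame.index)
        return OmicsFeatureMatrix(frame, layer_series, table)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
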