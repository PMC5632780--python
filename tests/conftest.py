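import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import symptomnet as sn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def csa_dataset():
    """Study-shaped preset: 17 symptoms, n=179, 14 incomplete rows."""
    ds, truth = sn.csa_ptsd_preset(seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def fast_glasso():
    """Short lambda path for bootstrap-heavy tests."""
    return sn.GlassoConfig(n_lambda=30)


def make_network(weights: np.ndarray, labels=None) -> sn.WeightedNetwork:
    """Wrap a raw symmetric weight matrix as a WeightedNetwork."""
    p = weights.shape[0]
    labels = labels or [f"v{i}" for i in range(p)]
    path = pd.DataFrame([{"lambda": 0.0, "n_edges": 0, "loglik": 0.0, "ebic": 0.0}])
    return sn.WeightedNetwork(weights, labels, 0.0, path)
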