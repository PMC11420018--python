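import numpy as np
import pytest

import ersnet as e
from ersnet.network import WeightedNetwork


@pytest.fixture(scope="session")
def default_data():
    """One default-config synthetic sample (N=376)."""
    return e.generate_dataset(e.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def network_table(default_data):
    return e.network_table(default_data)


@pytest.fixture(scope="session")
def fitted_mgm(network_table):
    """Mixed graphical model fitted once on the session sample."""
    return e.estimate_mgm(network_table, e.default_nodes(), e.EstimationSettings(cv_seed=11))


def make_mgm_net(
    node_ids,
    weights,
    kinds,
    means=None,
    sds=None,
    resid_sd=None,
) -> WeightedNetwork:
    """Hand-built mixed-model network with explicit training statistics."""
    p = len(node_ids)
    return WeightedNetwork(
        node_ids=list(node_ids),
        weights=np.asarray(weights, dtype=float),
        estimator_tag="mgm",
        kinds=list(kinds),
        means=np.asarray(means if means is not None else np.zeros(p), dtype=float),
        sds=np.asarray(sds if sds is not None else np.ones(p), dtype=float),
        residual_sd=np.asarray(resid_sd if resid_sd is not None else np.ones(p), dtype=float),
    )
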