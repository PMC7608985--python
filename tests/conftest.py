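import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cystquant as cq
from cystquant.synthetic import generate_lbp_training_set

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lbp_model():
    """Small-cyst texture classifier trained on generated patches.

    A compact grid keeps the fixture fast; hyper-parameter-grid behaviour
    itself is covered by the grid-search tests.
    """
    data = generate_lbp_training_set(60, seed=101)
    grid = cq.GridSearchConfig(c_exponents=(-1, 1, 3), gamma_exponents=(-7, -5, -3), seed=5)
    return cq.train_small_cyst_classifier(data, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
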