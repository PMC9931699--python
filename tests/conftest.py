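import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from citebest import (
    GroupDataset,
    ModelSpec,
    generate_group,
    pooled_prior_spec,
    sample_posterior,
)


@pytest.fixture(scope="session")
def two_group_spec() -> ModelSpec:
    """Well-separated two-group t data (mu 20 vs 10, sigma 5, nu 5)."""
    g1 = GroupDataset("reproducible", generate_group(200, 20.0, 5.0, 5.0, seed=1))
    g2 = GroupDataset("non_reproducible", generate_group(200, 10.0, 5.0, 5.0, seed=2))
    return ModelSpec(groups=(g1, g2), prior=pooled_prior_spec([g1, g2]))


@pytest.fixture(scope="session")
def fitted_trace(two_group_spec):
    """One moderately sized posterior trace shared across tests."""
    return sample_posterior(two_group_spec, draws=4000, chains=4, seed=11, tune=500)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231502)
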