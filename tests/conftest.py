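import numpy as np
import pytest

import distressdyn as dd


@pytest.fixture(scope="session")
def truth():
    return dd.default_truth()


@pytest.fixture(scope="session")
def obs_default(truth):
    """One synthetic observation set at the study's observation design."""
    return dd.generate_observations(dd.GeneratorConfig(truth=truth, seed=11))


@pytest.fixture(scope="session")
def fitted(obs_default):
    """One reduced-length unconstrained fit shared across read-only tests."""
    model = dd.PsychDistressModel(obs_default)
    res = model.fit(chains=4, iterations=1000, seed=5)
    return model, res


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
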