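import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iris_data():
    from sklearn.datasets import load_iris

    return load_iris().data


@pytest.fixture(scope="session")
def case2_bundle():
    from dfclust import gen_gaussian_case

    return gen_gaussian_case(2, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
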