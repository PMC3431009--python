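import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adhdconn.synthetic_data import GeneratorConfig, make_brain_template

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort configuration used across module tests."""
    return GeneratorConfig(
        n_subjects={"SiteA": {"TD": 2, "COMBINED": 2}},
        grid_dims=(14, 14, 8),
        parcel_size=(2, 2, 2),
        n_seeds=20,
        T=40,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_template(small_config):
    return make_brain_template(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
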