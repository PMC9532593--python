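import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from enzlim.synthetic import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def small_config() -> SurveyConfig:
    """A fast-to-generate survey used by pipeline and IO tests."""
    return SurveyConfig(
        n_sites=10, seed=42, n_taxa_bact=40, n_taxa_fungi=20, library_size=1000
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    return generate_survey(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
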