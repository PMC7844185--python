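import pytest
from hypothesis import HealthCheck, settings

import maternalcv as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cn_cohort():
    """Small Chinese-preset cohort shared across tests."""
    return m.generate_cohort(m.country_preset("CN", n=250, seed=7))


@pytest.fixture(scope="session")
def cn_scored(cn_cohort):
    return m.score_cohort(m.apply_inclusion_filter(cn_cohort))
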