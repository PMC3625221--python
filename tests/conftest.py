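import pytest
from hypothesis import HealthCheck, settings

import epiobs as eo

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def diseases() -> dict[str, eo.DiseaseFixture]:
    """All bundled disease parameter sets, loaded and validated once."""
    return {name: eo.load_fixture(name) for name in eo.BUNDLED_FIXTURES}


@pytest.fixture(scope="session")
def influenza(diseases) -> eo.DiseaseFixture:
    return diseases["influenza"]
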