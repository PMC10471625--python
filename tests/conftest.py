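import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from emfarm.defaults import (  # noqa: E402
    DEFAULT_EM_EURO,
    DEFAULT_WORKING_BASELINE,
    default_climate,
    default_grazing_params,
    default_uev_table,
)
from emfarm.synthetic import generate_worked_farm  # noqa: E402


@pytest.fixture(scope="session")
def uev_raw():
    return default_uev_table()


@pytest.fixture(scope="session")
def uev(uev_raw):
    """Default UEV table rescaled to the working baseline."""
    return uev_raw.rescaled(DEFAULT_WORKING_BASELINE)


@pytest.fixture(scope="session")
def climate():
    return default_climate()


@pytest.fixture(scope="session")
def grazing_params():
    return default_grazing_params()


@pytest.fixture(scope="session")
def em_euro():
    return DEFAULT_EM_EURO


@pytest.fixture()
def worked_farm():
    return generate_worked_farm()
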