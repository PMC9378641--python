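import numpy as np
import pytest

from landcarbon.toymodel import (
    ForcingSet,
    ToyModelParams,
    generate_forcing,
    run_quartet,
)
from landcarbon.containers import PoolFlags


@pytest.fixture(scope="session")
def forcing():
    """Default shared forcing, 1901-2020, seeded."""
    return generate_forcing(range(1901, 2021), seed=42)


@pytest.fixture(scope="session")
def quiet_forcing():
    """Noise-free forcing: climate anomaly is a pure trend."""
    return generate_forcing(
        range(1901, 2021), climate_spec={"sigma": 0.0}, seed=42
    )


@pytest.fixture(scope="session")
def flat_forcing():
    """All forcing axes flat at pre-industrial values (control world)."""
    years = np.arange(1901, 2021)
    return ForcingSet(
        years=years,
        co2=np.full(years.size, 280.0),
        t_anom=np.zeros(years.size),
        f_ag=np.full(years.size, 0.15),
        seed=0,
    )


@pytest.fixture(scope="session")
def default_params():
    return ToyModelParams()


@pytest.fixture(scope="session")
def single_pool_params():
    """No litter pool, temperature-insensitive soil, no climate effect."""
    return ToyModelParams(
        gamma=0.0, q10=1.0, flags=PoolFlags(has_litter=False)
    )


@pytest.fixture(scope="session")
def default_quartet(forcing, default_params):
    return run_quartet(default_params, forcing, "toy-default")


@pytest.fixture(scope="session")
def quiet_quartet(quiet_forcing, default_params):
    return run_quartet(default_params, quiet_forcing, "toy-quiet")
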