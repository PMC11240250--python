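import pytest

from phipchip import (
    TransportParams,
    alpha_chip,
    beta_chip,
    calibrate_film_depth,
    fumarate_13c1,
)


@pytest.fixture(scope="session")
def beta():
    return beta_chip()


@pytest.fixture(scope="session")
def alpha():
    return alpha_chip()


@pytest.fixture(scope="session")
def calibrated(beta):
    """Transport parameters with the film depth anchored on the beta chip
    saturating at 2 uL/min and 5 bar (the shared calibration)."""
    return calibrate_film_depth(beta, TransportParams(), pressure_bar=5.0)


@pytest.fixture(scope="session")
def fumarate():
    return fumarate_13c1()
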