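import pytest

from istlung import (
    SinewaveForcing,
    ThetaParams,
    VentilatorSettings,
    generate_measurement,
    preset,
)


@pytest.fixture(scope="session")
def settings():
    return VentilatorSettings()


@pytest.fixture(scope="session")
def forcing180():
    return SinewaveForcing(180.0)


@pytest.fixture(scope="session")
def forcing60():
    return SinewaveForcing(60.0)


@pytest.fixture(scope="session")
def healthy_theta() -> ThetaParams:
    return preset("healthy").theta


@pytest.fixture(scope="session")
def healthy_measurement(settings):
    """Noise-free synthetic IST record of the healthy verification patient."""
    return generate_measurement(preset("healthy").theta, settings)
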