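import numpy as np
import pytest

from neurice.params import DriveParams, build_morphology


@pytest.fixture(scope="session")
def drive():
    """Standard drive: mu=5 mV, sigma_s=1 mV, tau_s=5 ms."""
    return DriveParams(mu=5.0, sigma_s=1.0, tau_s=5.0)


@pytest.fixture(scope="session")
def one_dendrite():
    return build_morphology(mu=5.0, sigma_s=1.0)


@pytest.fixture(scope="session")
def two_dendrite():
    return build_morphology(mu=5.0, sigma_s=1.0, n=2)


@pytest.fixture(scope="session")
def dendrite_axon():
    """Dendrite + axon, trigger 30 um down the axon (Fig-5-style)."""
    return build_morphology(mu=5.0, sigma_s=3.0, a_ratio=0.25, x_th=30.0)


@pytest.fixture(scope="session")
def soma_model():
    return build_morphology(mu=5.0, sigma_s=3.0, a_ratio=0.25, rho_1=4.0,
                            x_th=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
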