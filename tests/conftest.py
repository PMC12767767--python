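import numpy as np
import pytest

from diffsizer import (
    Conditions,
    NoiseModel,
    Species,
    SpeciesMix,
    simulate_profiles,
)


@pytest.fixture(scope="session")
def water_25c() -> Conditions:
    return Conditions(temperature=298.15, viscosity=8.9e-4)


@pytest.fixture(scope="session")
def noiseless_2nm():
    """Noiseless single-species (2 nm) measurement set at the study geometry."""
    return simulate_profiles(SpeciesMix((Species(2.0),)))


@pytest.fixture(scope="session")
def noiseless_two_species():
    """Noiseless 1.5 nm + 3 nm mixture at the study geometry."""
    return simulate_profiles(SpeciesMix((Species(1.5), Species(3.0))))


@pytest.fixture()
def single_gaussian_profile():
    """Exact samples of one Gaussian (a=100, b=0, c=10) on x in [-150, 150]."""
    x = np.arange(-150.0, 151.0)
    y = 100.0 * np.exp(-((x / 10.0) ** 2))
    return x, y
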