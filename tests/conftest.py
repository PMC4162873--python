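import numpy as np
import pytest

from rfscreen.birdcage import TwoPortSpectrum
from rfscreen.circuit import FrequencyGrid, Resonator
from rfscreen.fixtures import coupling_family, nominal_reference


@pytest.fixture(scope="session")
def dielectric_ref() -> TwoPortSpectrum:
    """Nominal dielectric-load reference spectrum (noise-free)."""
    return nominal_reference("dielectric")


@pytest.fixture(scope="session")
def empty_ref() -> TwoPortSpectrum:
    return nominal_reference("empty")


@pytest.fixture(scope="session")
def family_45():
    """Coupling family with the wire at 45 deg (couples both ports equally)."""
    return coupling_family(45.0)


def random_resonator(rng: np.random.Generator, lossless: bool = False) -> Resonator:
    l = rng.uniform(1e-7, 1e-5)
    f0 = rng.uniform(50e6, 70e6)
    c = 1.0 / ((2 * np.pi * f0) ** 2 * l)
    r = 0.0 if lossless else rng.uniform(0.1, 100.0)
    return Resonator(l, c, r)


def rf_grid(n: int = 201) -> FrequencyGrid:
    return FrequencyGrid(55e6, 75e6, n)
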