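import numpy as np
import pytest

from periacuity import DisplayGeometry, NoiseSpec


@pytest.fixture(scope="session")
def geometry() -> DisplayGeometry:
    return DisplayGeometry()


@pytest.fixture(scope="session")
def small_noise() -> NoiseSpec:
    """A small-extent noise spec so composed trials stay cheap in tests."""
    return NoiseSpec(extent_deg=2.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
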