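import numpy as np
import pytest

from thraquant.camera import AttenuationTable, CollimatorSpec, DetectorSpec
from thraquant.unmixing import SpectralComponents


@pytest.fixture(scope="session")
def components20():
    """Component window integrals at 20 cm water (torso-phantom geometry)."""
    return SpectralComponents.prepare(20.0)


@pytest.fixture(scope="session")
def detector():
    return DetectorSpec()


@pytest.fixture(scope="session")
def collimator():
    return CollimatorSpec()


@pytest.fixture(scope="session")
def water():
    return AttenuationTable.water()
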