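import numpy as np
import pytest

from arterymech import HGOLayer, OpenSector, fixture


@pytest.fixture(scope="session")
def rabbit():
    """Rabbit carotid packaged fixture: stress-free sector + materials."""
    return fixture("rabbit_omega0")


@pytest.fixture(scope="session")
def rabbit_annulus():
    """Rabbit carotid unloaded annulus + materials."""
    return fixture("rabbit_omega_r")


@pytest.fixture(scope="session")
def media(rabbit):
    return rabbit.materials["media"]


@pytest.fixture(scope="session")
def adventitia(rabbit):
    return rabbit.materials["adventitia"]


@pytest.fixture
def toy_neo_hookean():
    """Single-material fibre-free ring for oracle comparisons.

    Both layers share one neo-Hookean material, so the two-layer machinery
    reduces to a homogeneous incompressible cylinder with a known ODE."""
    layer = HGOLayer(c=1.0, k1=0.0, k2=1.0, beta=0.0, name="toy")
    sector = OpenSector(R_i=1.0, R_m=1.1, R_o=1.2, alpha=90.0)
    return sector, {"media": layer, "adventitia": layer}


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240917))
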