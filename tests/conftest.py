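import numpy as np
import pytest

import dpdmelt as dm


@pytest.fixture(scope="session")
def ff():
    """Default lipid-nanoparticle force field (a_ii=25, a_ij=100)."""
    return dm.ForceFieldParams()


@pytest.fixture(scope="session")
def ff_conservative():
    """Thermostat switched off (gamma = sigma = 0): deterministic dynamics."""
    return dm.ForceFieldParams(gamma=0.0, sigma=0.0)


@pytest.fixture
def small_melt(ff):
    """A small equilibrable melt: 13-bead lipids at rho=3 in a D=6 box."""
    box = dm.BoxSpec(6.0, 3.0)
    n_lip = dm.lipid_count(3.0, 6.0, 13)
    topo = dm.build_lipid_topology(3, 10, n_lip)
    frame = dm.place_random_melt(topo, box, seed=11)
    frame = dm.init_velocities(frame, 1.0, seed=12)
    return topo, frame, box


def minimum_image(d, L):
    return d - L * np.rint(d / L)
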