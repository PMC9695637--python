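import numpy as np
import pytest

from chlamyorbit import CellGeometry, FluidParams, OrbitParams, generate_orbit_track
from chlamyorbit.stokes import reference_kinematics


@pytest.fixture(scope="session")
def geom():
    return CellGeometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidParams()


@pytest.fixture(scope="session")
def reference_cells():
    """The 12 published per-cell (ω, R) measurements as kinematics records."""
    return reference_kinematics()


@pytest.fixture
def clean_orbit_track():
    """Noiseless, beat-free orbit at the population-mean kinematics."""
    params = OrbitParams(R=1.16, omega=22.75, beat_amp=0.0, noise_sigma=0.0,
                         duration=1.0)
    return generate_orbit_track(params, seed=0), params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220927)
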