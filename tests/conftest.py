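import numpy as np
import pytest

from tcbackmap.frames import Frame, Trajectory
from tcbackmap.grids import GridSpec
from tcbackmap.synth import make_benchmark_system, simulate_langevin


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fine_grid():
    """High-resolution grid with sigma = 2 lattice spacings."""
    return GridSpec(d=33, r_grid=4.0, sigma=0.5, sigma_in_lattice_units=False)


@pytest.fixture(scope="session")
def coarse_grid():
    """Desk-scale grid used by the toy end-to-end protocol."""
    return GridSpec(d=17, r_grid=8.0, sigma=1.0, sigma_in_lattice_units=True)


@pytest.fixture(scope="session")
def tetramer():
    return make_benchmark_system("tetramer-2state")


@pytest.fixture(scope="session")
def dimer():
    return make_benchmark_system("dimer")


@pytest.fixture(scope="session")
def tetramer_short_traj(tetramer):
    """A short correlated tetramer trajectory (500 frames)."""
    return simulate_langevin(tetramer, 5000, np.random.default_rng(7))


@pytest.fixture
def random_frame(rng):
    return Frame(rng.normal(scale=0.8, size=(5, 3)))


def make_trajectory(n_frames, n_particles, seed=0, dt=1.0, scale=1.0):
    rng = np.random.default_rng(seed)
    return Trajectory(rng.normal(scale=scale, size=(n_frames, n_particles, 3)), dt=dt)
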