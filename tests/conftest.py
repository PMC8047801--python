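import numpy as np
import pytest

from mgff.synthetic import HoppingSpec, gen_hopping_traj
from mgff.trajectory import Trajectory


@pytest.fixture(scope="session")
def small_hopping():
    """One desk-scale shell-hopping trajectory with known exchange rate,
    shared across tests (generation is the expensive part)."""
    spec = HoppingSpec(
        k_true=8.0e5, N_Mg=10, N_H2O=555, t_sim=4e-6, dt=4e-9, box=4.2, seed=11
    )
    return spec, gen_hopping_traj(spec)


def single_water_traj(distances, box=5.0, dt=1.0):
    """One Mg at the box center and one water at prescribed distances along
    the x axis: the minimal fixture for indicator-function tests."""
    distances = np.asarray(distances, dtype=float)
    n = distances.size
    center = np.full((n, 1, 3), box / 2.0)
    water = center.copy()
    water[:, 0, 0] += distances
    return Trajectory(
        times=np.arange(n) * dt,
        coords={"Mg": center, "Ow": water},
        box=np.full((n, 3), box),
    )


@pytest.fixture
def make_single_water():
    return single_water_traj
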