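import numpy as np
import pytest

import mabsolkit as mk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ellipsoid_traj():
    """Rigid reference ellipsoid (Fab-like crystal dimensions), 10 frames."""
    spec = mk.EllipsoidProteinSpec(semi_axes=(3.9, 2.875, 2.275),
                                   n_beads=406, breathing_amplitude=0.0,
                                   seed=7)
    return mk.gen_protein_trajectory(spec, 10)


@pytest.fixture
def random_traj(rng):
    """Unstructured 50-atom, 4-frame trajectory for oracles/round trips."""
    n = 50
    coords = rng.uniform(1.0, 9.0, size=(4, n, 3))
    top = mk.Topology.simple(n, masses=rng.uniform(1.0, 20.0, n))
    return mk.Trajectory(top, coords, np.full(3, 10.0))


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()
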