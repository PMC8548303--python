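import numpy as np
import pytest

from ctma.geometry import TriangleMesh
from ctma.phantom import PhantomSpec, make_pair
from ctma.registration import RegistrationParams


@pytest.fixture(scope="session")
def fast_params():
    """Registration sizes for tests: enough points for sub-0.01 accuracy on
    noiseless phantoms, small enough to keep the suite quick."""
    return RegistrationParams(n_points=4000, fit_points=1500, max_iterations=60, seed=1)


@pytest.fixture(scope="session")
def clean_pair():
    """An undeformed, noiseless phantom pair (exactly mirror-symmetric)."""
    return make_pair(PhantomSpec())


@pytest.fixture(scope="session")
def short_spec():
    """A short leg for voxel-based tests (small grids, same voxel pitch physics)."""
    return PhantomSpec(tibia_length=120.0, fibula_length=110.0, plateau_radius=22.0,
                       fibula_offset=30.0)


@pytest.fixture
def tetrahedron():
    return TriangleMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
        label="tet",
    )


@pytest.fixture
def unit_cube():
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
         [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
         [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return TriangleMesh(v, f, label="cube")


def random_rigid(rng, max_angle_deg=180.0, max_shift=100.0):
    from scipy.spatial.transform import Rotation

    from ctma.geometry import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    return RigidTransform(r, rng.uniform(-max_shift, max_shift, 3))
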