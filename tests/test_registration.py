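"""Kabsch, coarse alignment, ICP and the surface-distance metric."""

import numpy as np
import pytest
import trimesh

from ctma.errors import RegistrationError
from ctma.geometry import (
    EulerAngles,
    RigidTransform,
    TriangleMesh,
    rotation_from_euler,
)
from ctma.phantom import PhantomSpec, make_leg
from ctma.registration import (
    RegistrationParams,
    icp_register,
    initial_align,
    kabsch,
    mean_surface_distance,
)

from conftest import random_rigid


@pytest.fixture(scope="module")
def tibia():
    return make_leg(PhantomSpec(), "right")["tibia"]


# ---------------------------------------------------------------------------
# Kabsch


def test_kabsch_identity_and_exact_recovery():
    rng = np.random.default_rng(0)
    p = rng.normal(size=(50, 3)) * 20
    t0 = kabsch(p, p)
    assert np.abs(t0.to_matrix() - np.eye(4)).max() < 1e-9
    truth = RigidTransform(rotation_from_euler(EulerAngles(0, 0, -30.0)), [1, 2, 3])
    t = kabsch(p, truth.apply(p))
    assert np.abs(t.to_matrix() - truth.to_matrix()).max() < 1e-9


def test_kabsch_rejects_degenerate_input():
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(RegistrationError, match="collinear"):
        kabsch(line, line)
    with pytest.raises(RegistrationError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(RegistrationError):
        kabsch(np.zeros((3, 3)), np.zeros((4, 3)))


def test_kabsch_never_returns_reflection():
    # near-planar points whose best orthogonal fit would be a reflection
    rng = np.random.default_rng(3)
    p = rng.normal(size=(10, 3)) * [10, 10, 0.01]
    q = p.copy()
    q[:, 2] *= -1  # mirrored
    t = kabsch(p, q)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_beats_random_search():
    """The closed-form least-squares fit must beat 10^6 random rigid guesses
    on a noisy 4-point problem."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(7)
    p = rng.normal(size=(4, 3)) * 10
    truth = random_rigid(rng, max_angle_deg=40, max_shift=5)
    q = truth.apply(p) + rng.normal(0, 0.5, size=(4, 3))
    t = kabsch(p, q)
    best = ((t.apply(p) - q) ** 2).sum()

    n = 1_000_000
    rots = Rotation.random(n, rng=rng).as_matrix()
    # centroid-matching translations give the random search its best shot
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    guess = np.einsum("nij,kj->nki", rots, p - pc) + qc
    costs = ((guess - q) ** 2).sum(axis=(1, 2))
    assert best <= costs.min() + 1e-12


# ---------------------------------------------------------------------------
# coarse alignment


def test_initial_align_identical_meshes(tibia):
    t = initial_align(tibia, tibia)
    assert t.rotation_angle_deg() < 1e-6
    disp = np.linalg.norm(t.apply(tibia.vertices) - tibia.vertices, axis=1)
    assert disp.max() < 1e-6


def test_initial_align_large_rotation(tibia):
    big = RigidTransform(rotation_from_euler(EulerAngles(0, 0, 170.0)), [30, -20, 10])
    moved = big.apply_mesh(tibia)
    t = initial_align(moved, tibia)
    residual = t.compose(big)
    assert residual.rotation_angle_deg() < 20.0


def test_initial_align_sphere_falls_back_to_centroids():
    s = trimesh.creation.icosphere(2)
    mesh = TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
    shifted = mesh.translated([5, 6, 7])
    t = initial_align(mesh, shifted)
    assert np.abs(t.rotation - np.eye(3)).max() < 1e-12  # centroid-only
    assert np.allclose(t.translation, [5, 6, 7], atol=0.1)


# ---------------------------------------------------------------------------
# ICP


def test_icp_identity_for_identical_meshes(tibia, fast_params):
    t, fit = icp_register(tibia, tibia, fast_params)
    assert t.rotation_angle_deg() < 1e-4
    assert np.linalg.norm(t.translation) < 1e-3
    assert fit.passed_gate and fit.converged
    assert fit.mean_distance < 1e-6


def test_icp_recovers_known_transform(tibia, fast_params):
    truth = RigidTransform(rotation_from_euler(EulerAngles(0, 0, 5.0)), [2.0, 0, 0])
    moved = truth.apply_mesh(tibia)
    t, fit = icp_register(moved, tibia, fast_params)
    # t should invert the applied motion
    residual = t.compose(truth)
    assert residual.rotation_angle_deg() < 0.01
    assert np.linalg.norm(residual.apply(tibia.vertices.mean(axis=0)) - tibia.vertices.mean(axis=0)) < 0.01
    assert fit.mean_distance < 1e-3


def test_icp_objective_non_increasing(tibia, fast_params):
    start = RigidTransform(rotation_from_euler(EulerAngles(3, -4, 6.0)), [5, -3, 2])
    moved = start.apply_mesh(tibia)
    _, fit = icp_register(moved, tibia, fast_params)
    h = np.array(fit.history)
    assert np.all(np.diff(h) <= 1e-9)


def test_icp_equivariance_under_pre_rotation(tibia, fast_params):
    """Pre-rotating the moving mesh changes the recovered transform by exactly
    that rotation's inverse composition."""
    start = RigidTransform(rotation_from_euler(EulerAngles(2, 1, -3.0)), [4, 1, -2])
    moved = start.apply_mesh(tibia)
    t1, _ = icp_register(moved, tibia, fast_params, initial="auto")
    extra = RigidTransform(rotation_from_euler(EulerAngles(0, 0, 10.0)), [0, 0, 0])
    moved2 = extra.apply_mesh(moved)
    t2, _ = icp_register(moved2, tibia, fast_params, initial="auto")
    assert np.abs(t2.compose(extra).to_matrix() - t1.to_matrix()).max() < 1e-6


def test_icp_reports_non_convergence_without_raising(tibia):
    # a tibia can never fit a small sphere: the solver must report failure,
    # not raise, and the gate must be false
    s = trimesh.creation.icosphere(2)
    ball = TriangleMesh(np.asarray(s.vertices) * 5.0 + [60, 0, 150], np.asarray(s.faces))
    params = RegistrationParams(n_points=2000, fit_points=500, max_iterations=2,
                                convergence_tol=1e-12, seed=0)
    _, fit = icp_register(tibia, ball, params, initial=RigidTransform.identity())
    assert not fit.converged
    assert not fit.passed_gate


def test_trimming_limits_artifact_influence(tibia, fast_params):
    """Welding a bump (~5% extra area) onto the moving surface must not move
    the recovered transform by more than 0.2 deg with 10% trimming."""
    s = trimesh.creation.icosphere(3)
    r_bump = 12.0
    bump = TriangleMesh(np.asarray(s.vertices) * r_bump + [78, 0, 180], np.asarray(s.faces))
    from ctma.geometry import merge_meshes

    with_bump = merge_meshes([tibia, bump])
    assert 0.02 < bump.area / tibia.area < 0.08
    t_clean, _ = icp_register(tibia, tibia, fast_params, initial=RigidTransform.identity())
    t_bump, _ = icp_register(with_bump, tibia, fast_params, initial=RigidTransform.identity())
    delta = t_bump.compose(t_clean.invert())
    assert delta.rotation_angle_deg() < 0.2


# ---------------------------------------------------------------------------
# surface distance


def test_mean_distance_identical_is_zero(tibia):
    assert mean_surface_distance(tibia, tibia, n=2000, seed=0) < 1e-9


def test_mean_distance_parallel_planes():
    plane = TriangleMesh([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]],
                         [[0, 1, 2], [0, 2, 3]])
    lifted = TriangleMesh(plane.vertices + [0, 0, 0.5], plane.faces)
    assert mean_surface_distance(plane, lifted, n=5000, seed=1) == pytest.approx(0.5, abs=1e-9)
    sym = mean_surface_distance(plane, lifted, n=5000, seed=1, symmetric=True)
    assert sym == pytest.approx(0.5, abs=1e-9)


def test_mean_distance_offset_spheres_matches_monte_carlo():
    """Mesh-based estimate against an analytic-surface Monte-Carlo oracle:
    for unit spheres 1 mm apart the exact point-to-sphere distance is
    | ||p - c2|| - 1 |."""
    s = trimesh.creation.icosphere(4)
    a = TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
    b = TriangleMesh(np.asarray(s.vertices) + [1.0, 0, 0], np.asarray(s.faces))
    got = mean_surface_distance(a, b, n=20_000, seed=2)
    rng = np.random.default_rng(9)
    u = rng.normal(size=(1_000_000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    oracle = np.abs(np.linalg.norm(u - [1.0, 0, 0], axis=1) - 1.0)
    se = oracle.std() / np.sqrt(len(oracle)) + oracle.mean() / np.sqrt(20_000)
    # icosphere(4) chord error ~2e-4
    assert abs(got - oracle.mean()) < 3 * se + 5e-4
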