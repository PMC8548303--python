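"""Mesh primitives, STL I/O, mirroring, sampling, COM and Euler conventions."""

import numpy as np
import pytest

from ctma.errors import MeshValidationError, STLParseError, TransformValidationError
from ctma.geometry import (
    EulerAngles,
    RigidTransform,
    TriangleMesh,
    center_of_mass,
    euler_angles,
    exact_surface_centroid,
    mirror_mesh,
    read_stl,
    rotation_from_euler,
    sample_surface,
    write_stl,
)
from ctma.phantom import PhantomSpec, make_leg


# ---------------------------------------------------------------------------
# STL I/O


def test_stl_roundtrip_tetrahedron(tetrahedron, tmp_path):
    p = tmp_path / "tet.stl"
    write_stl(tetrahedron, p)
    back = read_stl(p)
    assert back.n_vertices == 4 and back.n_faces == 4
    # same vertex set (order may differ after de-duplication)
    got = {tuple(np.round(v, 6)) for v in back.vertices}
    want = {tuple(np.round(v, 6)) for v in tetrahedron.vertices}
    assert got == want


def test_stl_ascii_binary_equivalent(unit_cube, tmp_path):
    pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
    write_stl(unit_cube, pa, ascii=True)
    write_stl(unit_cube, pb, ascii=False)
    va = {tuple(np.round(v, 5)) for v in read_stl(pa).vertices}
    vb = {tuple(np.round(v, 5)) for v in read_stl(pb).vertices}
    assert va == vb


def test_stl_roundtrip_preserves_signed_volume(tmp_path):
    tibia = make_leg(PhantomSpec(), "right")["tibia"]
    before = tibia.signed_volume()
    p = tmp_path / "tibia.stl"
    write_stl(tibia, p)
    after = read_stl(p).signed_volume()
    # STL stores 32-bit floats; divergence-theorem volume of a ~300 cm^3 bone
    # moves by far less than 1e-3 mm^3 per coordinate ulp, allow rounding
    assert after == pytest.approx(before, abs=0.5)
    assert abs(after - before) / abs(before) < 1e-5


def test_truncated_binary_stl_names_byte_offset(tmp_path):
    import struct

    p = tmp_path / "bad.stl"
    with open(p, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", 10))  # declares 10 triangles
        fh.write(b"\0" * 70)  # but truncates mid-facet
    with pytest.raises(STLParseError, match="byte offset"):
        read_stl(p)


def test_write_empty_mesh_rejected(tmp_path):
    empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(MeshValidationError):
        write_stl(empty, tmp_path / "empty.stl")


def test_mesh_invariant_validation():
    with pytest.raises(MeshValidationError, match="non-finite"):
        TriangleMesh([[0, 0, np.nan], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    with pytest.raises(MeshValidationError, match="out of range"):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 7]])


# ---------------------------------------------------------------------------
# mirroring


def test_mirror_reflects_about_plane():
    m = TriangleMesh([[1, 2, 3], [0, 0, 0], [0, 1, 0], [0, 0, 1]],
                     [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    assert np.allclose(mirror_mesh(m, 0.0).vertices[0], [-1, 2, 3])
    assert np.allclose(mirror_mesh(m, 5.0).vertices[0], [9, 2, 3])


def test_mirror_is_exact_involution(tetrahedron):
    twice = mirror_mesh(mirror_mesh(tetrahedron, 5.0), 5.0)
    assert np.array_equal(twice.vertices, tetrahedron.vertices)
    assert np.array_equal(twice.faces, tetrahedron.faces)


def test_mirror_preserves_positive_volume(unit_cube):
    assert unit_cube.signed_volume() > 0
    assert mirror_mesh(unit_cube, 0.0).signed_volume() == pytest.approx(
        unit_cube.signed_volume()
    )


def test_phantom_left_is_exact_mirror_of_right():
    spec = PhantomSpec()
    right = make_leg(spec, "right")["tibia"]
    left = make_leg(spec, "left")["tibia"]
    assert np.allclose(mirror_mesh(left, 0.0).vertices, right.vertices, atol=1e-12)


# ---------------------------------------------------------------------------
# surface sampling and centre of mass


def test_sample_surface_counts_and_planarity(tetrahedron):
    cloud = sample_surface(tetrahedron, 10_000, seed=0)
    assert len(cloud) == 10_000
    # every point lies on some face plane
    tri = tetrahedron.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    plane_dist = np.abs(np.einsum("pfi,fi->pf", cloud.points[:, None, :] - tri[None, :, 0, :], n))
    assert plane_dist.min(axis=1).max() < 1e-9


def test_sample_surface_area_proportional():
    # two faces with area ratio 9:1
    m = TriangleMesh(
        [[0, 0, 0], [9, 0, 0], [0, 2, 0], [10, 0, 0], [9, 2, 0]],
        [[0, 1, 2], [1, 3, 4]],
    )
    n = 100_000
    cloud = sample_surface(m, n, seed=3)
    frac_small = np.mean(cloud.points[:, 0] > 9.0)  # only the small face has x > 9
    p = 0.1
    sigma = np.sqrt(p * (1 - p) / n)
    assert abs(frac_small - p) < 4 * sigma + 0.002


def test_sample_surface_deterministic(tetrahedron):
    a = sample_surface(tetrahedron, 1000, seed=7).points
    b = sample_surface(tetrahedron, 1000, seed=7).points
    assert np.array_equal(a, b)
    c = sample_surface(tetrahedron, 1000, seed=8).points
    assert not np.array_equal(a, c)


def test_sample_zero_area_rejected():
    degenerate = TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
    with pytest.raises(MeshValidationError):
        sample_surface(degenerate, 10, seed=0)


def test_com_sphere_and_translation_equivariance():
    import trimesh

    s = trimesh.creation.icosphere(3)
    mesh = TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
    com = center_of_mass(mesh, n=100_000, seed=0)
    assert np.linalg.norm(com) < 0.01
    shifted = mesh.translated([10, 0, 0])
    com2 = center_of_mass(shifted, n=100_000, seed=0)
    assert np.allclose(com2 - com, [10, 0, 0], atol=1e-12)


def test_com_matches_exact_box_centroid(unit_cube):
    # lop-sided box: scale the cube, exact surface centroid from the oracle
    box = TriangleMesh(unit_cube.vertices * [4.0, 2.0, 1.0], unit_cube.faces)
    exact = exact_surface_centroid(box)
    n = 200_000
    com = center_of_mass(box, n=n, seed=5)
    # per-axis standard error of an area-uniform sample mean
    pts = sample_surface(box, n, seed=5).points
    se = pts.std(axis=0) / np.sqrt(n)
    assert np.all(np.abs(com - exact) < 3 * se + 1e-9)


def test_com_standard_error_scales_as_inverse_sqrt_n(unit_cube):
    box = TriangleMesh(unit_cube.vertices * [4.0, 2.0, 1.0], unit_cube.faces)
    exact = exact_surface_centroid(box)
    reps = 40
    err_n = np.array([center_of_mass(box, 2000, seed=s) - exact for s in range(reps)])
    err_4n = np.array([center_of_mass(box, 8000, seed=1000 + s) - exact for s in range(reps)])
    r = np.linalg.norm(err_n, axis=1).std() / np.linalg.norm(err_4n, axis=1).std()
    assert 2.0 * 0.8 < r < 2.0 * 1.25  # factor-of-2 drop within ~20-25%


# ---------------------------------------------------------------------------
# rigid transforms


def test_transform_algebra_identity_compose_invert():
    rng = np.random.default_rng(0)
    t = RigidTransform(
        rotation=rotation_from_euler(EulerAngles(10.0, -20.0, 30.0)),
        translation=[1.0, -2.0, 3.0],
    )
    ident = RigidTransform.identity()
    assert np.allclose(ident.compose(ident).to_matrix(), np.eye(4))
    pts = rng.normal(size=(100, 3)) * 50
    back = t.invert().apply(t.apply(pts))
    assert np.abs(back - pts).max() < 1e-9
    # compose semantics: apply(compose(t1,t2), p) == apply(t1, apply(t2, p))
    t2 = RigidTransform(rotation_from_euler(EulerAngles(0.0, 5.0, 0.0)), [0, 1, 0])
    assert np.allclose(t.compose(t2).apply(pts), t.apply(t2.apply(pts)))


def test_two_quarter_turns_make_half_turn():
    q = RigidTransform(rotation_from_euler(EulerAngles(0, 0, 90.0)), np.zeros(3))
    half = q.compose(q)
    assert np.allclose(half.rotation, rotation_from_euler(EulerAngles(0, 0, 180.0)), atol=1e-12)


def test_non_rigid_matrix_rejected():
    with pytest.raises(TransformValidationError):
        RigidTransform(np.eye(3) * 1.01, np.zeros(3))
    with pytest.raises(TransformValidationError):
        RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))  # reflection


def test_transform_json_roundtrip(tmp_path):
    t = RigidTransform(rotation_from_euler(EulerAngles(1.0, 2.0, 3.0)), [4, 5, 6])
    p = tmp_path / "t.json"
    t.to_json(p)
    back = RigidTransform.from_json(p)
    assert np.allclose(back.to_matrix(), t.to_matrix(), atol=1e-12)


# ---------------------------------------------------------------------------
# Euler decomposition (clinical sign convention)


def test_euler_identity_is_zero():
    e = euler_angles(RigidTransform.identity())
    assert (e.rotX, e.rotY, e.rotZ) == (0.0, 0.0, 0.0)
    assert not e.gimbal_lock


def test_right_hand_rotation_reads_negative_clinical():
    # a +10 deg right-hand rotation about Z is clinically -10 deg
    a = np.radians(10.0)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    e = euler_angles(RigidTransform(rz, np.zeros(3)))
    assert e.rotZ == pytest.approx(-10.0, abs=1e-9)
    assert abs(e.rotX) < 1e-9 and abs(e.rotY) < 1e-9


@pytest.mark.parametrize("angles", [(0, 0, 0), (10, 20, 30), (-45, 60, -80), (89, -89, 179)])
def test_euler_roundtrip(angles):
    e = EulerAngles(*map(float, angles))
    r = rotation_from_euler(e)
    back = euler_angles(RigidTransform(r, np.zeros(3)))
    assert np.allclose(back.as_array(), e.as_array(), atol=1e-7)
    assert np.abs(rotation_from_euler(back) - r).max() < 1e-9


def test_small_angles_insensitive_to_composition_order():
    """At <= 2 deg the decomposition recovers per-axis angles regardless of the
    order the physical rotations were applied in (brute force over all 6)."""
    import itertools

    from ctma.geometry import _axis_rotation

    angs = {"x": 1.0, "y": -1.5, "z": 0.8}  # right-hand degrees
    mats = {"x": _axis_rotation(0, angs["x"]), "y": _axis_rotation(1, angs["y"]),
            "z": _axis_rotation(2, angs["z"])}
    expected = EulerAngles(-angs["x"], -angs["y"], -angs["z"]).as_array()
    for order in itertools.permutations("xyz"):
        r = mats[order[2]] @ mats[order[1]] @ mats[order[0]]
        got = euler_angles(RigidTransform(r, np.zeros(3))).as_array()
        assert np.abs(got - expected).max() < 0.05


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.floats(-85, 85, allow_nan=False),
        st.floats(-85, 85, allow_nan=False),
        st.floats(-179, 179, allow_nan=False),
    )
    def test_euler_roundtrip_property(rx, ry, rz):
        """Away from gimbal lock the decomposition is the unique inverse of
        the angle-to-rotation map."""
        e = EulerAngles(rx, ry, rz)
        back = euler_angles(RigidTransform(rotation_from_euler(e), np.zeros(3)))
        assert np.allclose(back.as_array(), e.as_array(), atol=1e-6)
        assert np.abs(rotation_from_euler(back) - rotation_from_euler(e)).max() < 1e-9

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_gimbal_lock_flagged_and_split_by_convention():
    r = rotation_from_euler(EulerAngles(0.0, 90.0, 25.0))
    e = euler_angles(RigidTransform(r, np.zeros(3)))
    assert e.gimbal_lock
    assert e.rotX == 0.0
    assert e.rotY == pytest.approx(90.0, abs=1e-6)
    # the X/Z split is conventional but the rotation must rebuild exactly
    assert np.abs(rotation_from_euler(e) - r).max() < 1e-9
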