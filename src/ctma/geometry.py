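"""Mesh and transform primitives in the canonical patient frame.

All geometry in this package lives in a single right-handed patient frame,
in millimetres:

* ``X`` points from the patient's left to the right,
* ``Y`` points from front (anterior) to back (posterior),
* ``Z`` points from the feet to the head.

This is the frame in which the clinical readings of the six deformity
parameters are defined: rotation about ``Z`` is internal/external rotation
(torsion), rotation about ``Y`` is varus/valgus, rotation about ``X`` is
recurvatum/antecurvatum.

Rotation angles are reported with the clinical sign convention used
throughout the package: an angle is *positive* for a rotation that appears
clockwise to an observer looking along the positive axis from its tip
toward the origin.  Numerically this is the negation of the right-hand-rule
angle; :func:`euler_angles` and :func:`rotation_from_euler` are exact
inverses of each other under this convention.  Decomposition uses fixed
(extrinsic) axes in the order X, then Y, then Z; at the magnitudes this
package is designed for (a few degrees) the ordering is immaterial.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshValidationError, STLParseError, TransformValidationError

__all__ = [
    "TriangleMesh",
    "PointCloud",
    "VoxelVolume",
    "RigidTransform",
    "EulerAngles",
    "read_stl",
    "write_stl",
    "mirror_mesh",
    "merge_meshes",
    "sample_surface",
    "center_of_mass",
    "exact_surface_centroid",
    "euler_angles",
    "rotation_from_euler",
]

_RIGID_TOL = 1e-9


# ---------------------------------------------------------------------------
# meshes


@dataclasses.dataclass
class TriangleMesh:
    """A triangle surface of one bone (or bone group) in patient coordinates (mm).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in millimetres.
    faces : (m, 3) int array
        Triangles as vertex-index triples with consistent outward winding
        (a closed mesh has positive signed volume).
    label : str
        Free-text bone or segment name ("tibia", "right distal", ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.size and not np.isfinite(self.vertices).all():
            raise MeshValidationError(f"mesh {self.label!r}: non-finite vertex coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshValidationError(f"mesh {self.label!r}: face index out of range")

    # -- derived quantities -------------------------------------------------

    def as_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` (no processing, shared arrays)."""
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Signed volume by the divergence theorem (exact for closed meshes).

        Positive for a closed mesh with outward winding; meaningless for
        open surfaces.
        """
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of per-axis (min, max)."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- editing ------------------------------------------------------------

    def flipped(self) -> "TriangleMesh":
        """Mesh with reversed face winding."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy(), self.label)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces.copy(), self.label)

    def validate_for_registration(self) -> None:
        """Raise unless the mesh is usable as a registration surface."""
        if self.n_vertices < 4 or self.n_faces < 4:
            raise MeshValidationError(
                f"mesh {self.label!r}: needs >= 4 vertices and >= 4 faces for registration "
                f"(got {self.n_vertices}/{self.n_faces})"
            )
        if self.area <= 0.0:
            raise MeshValidationError(f"mesh {self.label!r}: zero surface area")


def merge_meshes(meshes, label: str = "") -> TriangleMesh:
    """Concatenate several surfaces into one (indices re-offset, labels joined)."""
    meshes = list(meshes)
    if not meshes:
        raise MeshValidationError("cannot merge an empty list of meshes")
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += m.n_vertices
    return TriangleMesh(
        np.vstack(verts), np.vstack(faces), label or "+".join(m.label for m in meshes)
    )


@dataclasses.dataclass
class PointCloud:
    """Points sampled on a surface (mm)."""

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 1:
            raise MeshValidationError("point cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise MeshValidationError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass
class VoxelVolume:
    """A CT intensity grid in Hounsfield units.

    ``hu`` is indexed ``[ix, iy, iz]`` along the canonical X/Y/Z axes; voxel
    centre ``(ix, iy, iz)`` sits at ``origin + index * spacing`` (mm).
    """

    hu: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: str = "canonical"  # X left->right, Y front->back, Z feet->head

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.hu.ndim != 3 or self.hu.size == 0:
            raise MeshValidationError("volume grid must be a non-empty 3-D array")
        if not (self.spacing > 0).all():
            raise MeshValidationError("voxel spacing must be positive on all axes")
        if not np.isfinite(self.hu).all():
            raise MeshValidationError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple:
        return self.hu.shape

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def world_to_index(self, pos) -> np.ndarray:
        return (np.asarray(pos, float) - self.origin) / self.spacing


# ---------------------------------------------------------------------------
# STL I/O (binary and ASCII; coordinates are millimetres — STL has no units)


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file.

    Duplicate per-facet vertices are merged so a watertight export reads
    back watertight.  Malformed files raise :class:`STLParseError` naming
    the byte offset where the structure breaks when it can be determined.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    _precheck_stl(path)
    try:
        m = trimesh.load(str(path), file_type="stl", process=True)
    except Exception as exc:  # trimesh raises various types on bad input
        raise STLParseError(f"{path}: failed to parse STL (byte offset unknown): {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise MeshValidationError(f"{path}: STL contains no triangles")
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces), label=path.stem)


def _precheck_stl(path: Path) -> None:
    """Cheap structural check so truncation errors report a byte offset."""
    size = path.stat().st_size
    if size < 15:
        raise STLParseError(f"{path}: truncated at byte {size}; not a valid STL")
    with open(path, "rb") as fh:
        head = fh.read(84)
    if head[:5].lower() == b"solid" and not _looks_binary(head, size):
        return  # ASCII; leave detailed parsing to the reader
    if size < 84:
        raise STLParseError(f"{path}: binary STL truncated at byte {size} (header needs 84)")
    (n,) = struct.unpack("<I", head[80:84])
    expected = 84 + 50 * n
    if size != expected:
        off = min(size, expected)
        raise STLParseError(
            f"{path}: binary STL declares {n} triangles ({expected} bytes) but file has "
            f"{size} bytes; structure breaks at byte offset {off}"
        )


def _looks_binary(head: bytes, size: int) -> bool:
    # Some binary files start with 'solid' in the comment header; trust the
    # triangle-count arithmetic over the magic word.
    if len(head) < 84:
        return False
    (n,) = struct.unpack("<I", head[80:84])
    return size == 84 + 50 * n


def write_stl(mesh: TriangleMesh, path, ascii: bool = False) -> None:
    """Write a mesh as STL (binary by default, ASCII on request)."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    tm = mesh.as_trimesh()
    tm.export(str(path), file_type="stl_ascii" if ascii else "stl")


# ---------------------------------------------------------------------------
# mirroring


def mirror_mesh(mesh: TriangleMesh, plane_offset_x: float = 0.0) -> TriangleMesh:
    """Reflect a mesh about the sagittal plane ``x = plane_offset_x``.

    The face winding is flipped so a closed mesh keeps positive signed
    volume; applying the same mirror twice returns the input bit-exactly.
    """
    v = mesh.vertices.copy()
    v[:, 0] = 2.0 * plane_offset_x - v[:, 0]
    return TriangleMesh(v, mesh.faces[:, ::-1].copy(), label=f"mirror({mesh.label})")


# ---------------------------------------------------------------------------
# surface sampling and centre of mass


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_surface(mesh: TriangleMesh, n: int, seed=0) -> PointCloud:
    """Draw ``n`` area-uniform points on a surface.

    Faces are chosen with probability proportional to area and points
    placed barycentric-uniformly within each face; the draw is
    deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0.0:
        raise MeshValidationError(f"mesh {mesh.label!r}: zero surface area, cannot sample")
    rng = _rng(seed)
    face_idx = rng.choice(len(areas), size=n, p=areas / total)
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    t = mesh.triangles()[face_idx]
    pts = (1 - r1)[:, None] * t[:, 0] + (r1 * (1 - r2))[:, None] * t[:, 1] + (r1 * r2)[:, None] * t[:, 2]
    return PointCloud(pts, source=mesh.label)


def center_of_mass(mesh: TriangleMesh, n: int = 10_000, seed=0) -> np.ndarray:
    """Surface centre of mass from an area-uniform point sample.

    The centre is the mean of ``n`` sampled surface points — a Monte-Carlo
    estimate of the area-weighted surface centroid, deliberately defined
    through the same point machinery the registration uses.  It converges
    to :func:`exact_surface_centroid` as ``n`` grows and is exactly
    translation-equivariant for a fixed seed.
    """
    return sample_surface(mesh, n, seed=seed).points.mean(axis=0)


def exact_surface_centroid(mesh: TriangleMesh) -> np.ndarray:
    """Closed-form area-weighted surface centroid (cross-check oracle)."""
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0.0:
        raise MeshValidationError(f"mesh {mesh.label!r}: zero surface area")
    centroids = mesh.triangles().mean(axis=1)
    return (areas[:, None] * centroids).sum(axis=0) / total


# ---------------------------------------------------------------------------
# rigid transforms


@dataclasses.dataclass
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise TransformValidationError(f"rotation not orthonormal (|R'R - I| = {err:.3g})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise TransformValidationError(f"rotation determinant {det:.9f} != +1 (reflection?)")
        # snap to the nearest exact rotation so long compositions stay rigid
        if err > _RIGID_TOL:
            u, _, vt = np.linalg.svd(self.rotation)
            self.rotation = u @ vt

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=np.float64).reshape(4, 4)
        if np.abs(m[3] - [0, 0, 0, 1]).max() > 1e-9:
            raise TransformValidationError("last row of a rigid 4x4 matrix must be [0,0,0,1]")
        return cls(m[:3, :3], m[:3, 3])

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return TriangleMesh(self.apply(mesh.vertices), mesh.faces.copy(), mesh.label)

    def apply_cloud(self, cloud: PointCloud) -> PointCloud:
        return PointCloud(self.apply(cloud.points), cloud.source)

    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) irrespective of axis."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    # -- serialization (4x4 row-major in JSON) ------------------------------

    def to_json(self, path=None) -> str:
        payload = json.dumps({"matrix": self.to_matrix().tolist()}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "RigidTransform":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and Path(str(source)).is_file() else str(source)
        return cls.from_matrix(np.array(json.loads(text)["matrix"]))


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Functional alias: ``apply(compose(t1, t2), p) == apply(t1, apply(t2, p))``."""
    return t1.compose(t2)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


# ---------------------------------------------------------------------------
# Euler decomposition (clinical sign convention)


@dataclasses.dataclass
class EulerAngles:
    """Rotations about the canonical axes, degrees, clinical sign convention.

    ``rotX`` reads as recurvatum/antecurvatum, ``rotY`` as varus/valgus and
    ``rotZ`` as internal/external rotation.  ``gimbal_lock`` is set when
    ``|rotY|`` is within ~1e-6 degrees of 90 and the X/Z split is fixed by
    the convention ``rotX = 0``.
    """

    rotX: float
    rotY: float
    rotZ: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.rotX, self.rotY, self.rotZ], dtype=float)


def _axis_rotation(axis: int, deg: float) -> np.ndarray:
    """Right-hand-rule rotation matrix about a canonical axis."""
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def rotation_from_euler(angles: EulerAngles) -> np.ndarray:
    """Rotation matrix for clinical-convention angles, fixed axes X then Y then Z.

    Clinical angles are negated right-hand angles, so the matrix is
    ``Rz(-rotZ) @ Ry(-rotY) @ Rx(-rotX)``.
    """
    return (
        _axis_rotation(2, -angles.rotZ)
        @ _axis_rotation(1, -angles.rotY)
        @ _axis_rotation(0, -angles.rotX)
    )


def euler_angles(t: RigidTransform | np.ndarray) -> EulerAngles:
    """Decompose a rotation into clinical-convention fixed-axis X·Y·Z angles.

    Inverse of :func:`rotation_from_euler` to better than 1e-9 radians away
    from gimbal lock.  At ``|rotY| = 90°`` the decomposition is degenerate;
    the result is flagged and ``rotX`` set to zero by convention.
    """
    r = t.rotation if isinstance(t, RigidTransform) else np.asarray(t, float).reshape(3, 3)
    # right-hand extrinsic xyz:  R = Rz(c) @ Ry(b) @ Rx(a),  R[2,0] = -sin(b)
    sb = -r[2, 0]
    sb = float(np.clip(sb, -1.0, 1.0))
    lock = abs(abs(sb) - 1.0) < 1e-12  # ~1e-6 deg from +/-90
    b = np.arcsin(sb)
    if lock:
        a = 0.0
        c = float(np.arctan2(-r[0, 1], r[1, 1]))
    else:
        a = float(np.arctan2(r[2, 1], r[2, 2]))
        c = float(np.arctan2(r[1, 0], r[0, 0]))
    rx, ry, rz = -np.degrees(a), -np.degrees(b), -np.degrees(c)  # clinical = -right-hand
    return EulerAngles(_wrap_deg(rx), _wrap_deg(ry), _wrap_deg(rz), gimbal_lock=bool(lock))


def _wrap_deg(x: float) -> float:
    """Wrap an angle into (-180, 180]."""
    y = (-float(x) + 180.0) % 360.0
    return float(-(y - 180.0)) if y != 0.0 else 180.0
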