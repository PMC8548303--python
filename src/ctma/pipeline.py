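"""The mirrored-contralateral deformity analysis.

Workflow for one subject: mirror the left lower leg through a sagittal
plane, rigidly register its proximal segment onto the right proximal
segment (the stationary reference), carry the whole mirrored leg along
with that alignment, then register the pre-aligned distal segment onto the
right distal segment.  The residual distal transform *is* the side-to-side
deformity; it is reported as three centre-of-mass translations (mm) and
three fixed-axis rotations (degrees) with their clinical readings:

=====  ==========================  ==========================
axis   rotation reads as           translation reads as
=====  ==========================  ==========================
X      recurvatum / antecurvatum   left-right shift
Y      varus / valgus              antero-posterior shift
Z      internal / external torsion proximal-distal shift
=====  ==========================  ==========================

Rotations are expressed in the proximally-aligned patient frame, and the
translation is the displacement of the distal segment's centre of mass
under the residual transform — a quantity independent of the coordinate
origin, unlike the transform's raw translation column.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import CTMAError, MeshValidationError, OrientationError
from .geometry import (
    EulerAngles,
    TriangleMesh,
    center_of_mass,
    euler_angles,
    merge_meshes,
    mirror_mesh,
)
from .registration import FitQuality, RegistrationParams, icp_register, initial_align

__all__ = [
    "LegPair",
    "SegmentDefinition",
    "DeformityReport",
    "COHORT_COLUMNS",
    "split_segments",
    "analyze_pair",
    "batch_analyze",
]

COHORT_COLUMNS = [
    "subject",
    "COMX_mm",
    "COMY_mm",
    "COMZ_mm",
    "ROTX_deg",
    "ROTY_deg",
    "ROTZ_deg",
    "prox_fit_mm",
    "dist_fit_mm",
]


@dataclasses.dataclass
class LegPair:
    """Right and left lower-leg surfaces of one subject (label -> mesh, mm)."""

    right: dict
    left: dict
    subject: str = ""

    def __post_init__(self) -> None:
        if not self.right or not self.left:
            raise MeshValidationError(f"subject {self.subject!r}: both sides must be nonempty")

    def right_merged(self) -> TriangleMesh:
        return merge_meshes(self.right.values(), label=f"{self.subject}:right")

    def left_merged(self) -> TriangleMesh:
        return merge_meshes(self.left.values(), label=f"{self.subject}:left")

    def swapped(self) -> "LegPair":
        """The same subject with the sides exchanged (for antisymmetry checks)."""
        return LegPair(right=dict(self.left), left=dict(self.right), subject=self.subject)


@dataclasses.dataclass
class SegmentDefinition:
    """Fractions of the bone's Z-extent forming the two registration segments.

    The proximal fraction is measured down from the proximal (knee) end and
    captures the tibia plateau, fibular head and proximal diaphysis; the
    distal fraction is measured up from the distal (ankle) end and captures
    the plafond, distal fibula and distal diaphysis.
    """

    proximal_fraction: float = 0.30
    distal_fraction: float = 0.30

    def __post_init__(self) -> None:
        for f in (self.proximal_fraction, self.distal_fraction):
            if not (0.0 < f <= 0.5):
                raise ValueError("segment fractions must lie in (0, 0.5]")
        if self.proximal_fraction + self.distal_fraction > 1.0 + 1e-12:
            raise ValueError("segments overlap: fractions sum above 1")


@dataclasses.dataclass
class DeformityReport:
    """The six side-to-side deformity parameters plus registration quality."""

    comX: float
    comY: float
    comZ: float
    rotX: float
    rotY: float
    rotZ: float
    proximal_fit: FitQuality
    distal_fit: FitQuality
    subject: str = ""
    reliable: bool = True
    gimbal_lock: bool = False

    @property
    def clinical(self) -> dict:
        return {
            "rotZ": "external rotation" if self.rotZ >= 0 else "internal rotation",
            "rotY": "varus" if self.rotY >= 0 else "valgus",
            "rotX": "recurvatum" if self.rotX >= 0 else "antecurvatum",
        }

    def values(self) -> np.ndarray:
        return np.array([self.comX, self.comY, self.comZ, self.rotX, self.rotY, self.rotZ])

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "COMX_mm": self.comX,
            "COMY_mm": self.comY,
            "COMZ_mm": self.comZ,
            "ROTX_deg": self.rotX,
            "ROTY_deg": self.rotY,
            "ROTZ_deg": self.rotZ,
            "prox_fit_mm": self.proximal_fit.mean_distance,
            "dist_fit_mm": self.distal_fit.mean_distance,
            "reliable": self.reliable,
            "clinical": self.clinical,
        }


# ---------------------------------------------------------------------------
# segment splitting


def _clip_faces_z(mesh: TriangleMesh, z_cut: float, keep_above: bool, axis=None) -> TriangleMesh:
    """Keep the part of a surface on one side of the plane ``coord = z_cut``.

    ``coord`` is the Z coordinate, or the projection onto ``axis`` when
    given.  Faces straddling the plane are clipped exactly at it
    (Sutherland–Hodgman per triangle); the cut rim is left open, which is
    fine for sampling-based registration.
    """
    sign = 1.0 if keep_above else -1.0
    v, f = mesh.vertices, mesh.faces
    coord = v[:, 2] if axis is None else v @ axis
    side = sign * (coord - z_cut)  # >= 0 means keep
    inside = side >= 0
    n_in = inside[f].sum(axis=1)

    kept = list(f[n_in == 3])
    new_verts = [v]
    offset = len(v)

    def cut_point(i, j):
        # intersection of edge (i, j) with the plane
        ti = side[i] / (side[i] - side[j])
        return v[i] + ti * (v[j] - v[i])

    for tri in f[(n_in == 1) | (n_in == 2)]:
        ins = [i for i in tri if inside[i]]
        outs = [i for i in tri if not inside[i]]
        if len(ins) == 1:
            a = ins[0]
            # order the outs to preserve winding: rotate tri so a is first
            idx = list(tri)
            while idx[0] != a:
                idx = idx[1:] + idx[:1]
            _, b, c = idx
            p_ab, p_ca = cut_point(a, b), cut_point(c, a)
            new_verts.append(np.array([p_ab, p_ca]))
            kept.append(np.array([a, offset, offset + 1]))
            offset += 2
        else:
            c = outs[0]
            idx = list(tri)
            while idx[2] != c:
                idx = idx[1:] + idx[:1]
            a, b, _ = idx
            p_bc, p_ca = cut_point(b, c), cut_point(c, a)
            new_verts.append(np.array([p_bc, p_ca]))
            kept.append(np.array([a, b, offset]))
            kept.append(np.array([a, offset, offset + 1]))
            offset += 2

    if not kept:
        raise MeshValidationError(f"mesh {mesh.label!r}: nothing on the requested side of z={z_cut:.1f}")
    out = TriangleMesh(np.vstack(new_verts), np.vstack(kept), label=mesh.label)
    return _drop_unused_vertices(out)


def _drop_unused_vertices(mesh: TriangleMesh) -> TriangleMesh:
    used = np.unique(mesh.faces)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[mesh.faces], mesh.label)


def _long_axis(mesh: TriangleMesh) -> np.ndarray:
    """The leg's long axis: first principal axis of area-weighted face centroids.

    Exactly rigid- and mirror-equivariant (no sampling), so mirror-partner
    legs are cut into exact partner segments whatever the global pose.
    The sign is chosen so the *proximal* end — the fatter one, carrying the
    tibia plateau and fibular head — sits at high projection values, which
    reduces to the feet-to-head +Z convention for an upright leg; for a
    shape whose two ends are indistinguishable the +Z sense is kept.
    """
    w = mesh.face_areas()
    c = mesh.triangles().mean(axis=1)
    mu = (w[:, None] * c).sum(axis=0) / w.sum()
    d = c - mu
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    vals, vecs = np.linalg.eigh(cov)
    u = vecs[:, np.argmax(vals)]
    s = c @ u
    lo, hi = s.min(), s.max()
    band = 0.15 * (hi - lo)
    spread = []
    for sel in (s <= lo + band, s >= hi - band):
        dd = d[sel] - np.outer(d[sel] @ u, u)
        ww = w[sel]
        spread.append(np.sqrt((ww * (dd**2).sum(axis=1)).sum() / ww.sum()))
    if abs(spread[1] - spread[0]) > 0.05 * max(spread):
        if spread[0] > spread[1]:  # fat (proximal) end must be at high values
            u = -u
    elif u[2] < 0:
        u = -u
    return u


def split_segments(
    meshes, seg_def: SegmentDefinition | None = None, axis="z"
) -> tuple:
    """Cut a leg (one merged mesh, or several) into proximal and distal segments.

    The extent is taken jointly over all meshes so tibia and fibula are
    cut at the same anatomical levels.  With ``axis="z"`` the cut runs
    along canonical Z (the leg must stand roughly feet-to-head);
    ``axis="auto"`` cuts along the leg's own long axis (see
    :func:`_long_axis`) so the split is invariant to the global pose; an
    explicit 3-vector is also accepted.
    """
    seg_def = seg_def or SegmentDefinition()
    if isinstance(meshes, TriangleMesh):
        meshes = [meshes]
    else:
        meshes = list(meshes.values() if isinstance(meshes, dict) else meshes)
    if isinstance(axis, str):
        u = None if axis == "z" else _long_axis(merge_meshes(meshes))
    else:
        u = np.asarray(axis, float)
        u = u / np.linalg.norm(u)
    proj = [m.vertices[:, 2] if u is None else m.vertices @ u for m in meshes]
    z_lo = min(p.min() for p in proj)
    z_hi = max(p.max() for p in proj)
    length = z_hi - z_lo
    z_prox = z_hi - seg_def.proximal_fraction * length
    z_dist = z_lo + seg_def.distal_fraction * length
    prox = merge_meshes(
        [_clip_faces_z(m, z_prox, keep_above=True, axis=u) for m in meshes], label="proximal"
    )
    dist = merge_meshes(
        [_clip_faces_z(m, z_dist, keep_above=False, axis=u) for m in meshes], label="distal"
    )
    return prox, dist


# ---------------------------------------------------------------------------
# the analysis proper


def analyze_pair(
    pair: LegPair,
    seg_def: SegmentDefinition | None = None,
    reg_params: RegistrationParams | None = None,
    mirror_plane_x: float | None = None,
    com_points: int = 10_000,
) -> DeformityReport:
    """Run the full mirrored-contralateral analysis for one subject.

    Steps: (1) mirror the left leg about ``x = mirror_plane_x`` (default:
    the mid-plane of the joint bounding box of both legs — the offset is
    arbitrary because the proximal registration absorbs it); (2) register
    the mirrored-left proximal segment onto the right proximal segment;
    (3) apply that transform to the whole mirrored left leg; (4) register
    the pre-aligned mirrored-left distal segment onto the right distal
    segment; (5) decompose the residual transform into clinical Euler
    angles and the displacement of the distal centre of mass.

    A report whose registrations failed the mean-distance gate (or did not
    converge) is flagged ``reliable = False`` but still carries values.
    An :class:`OrientationError` is raised when the proximal registration
    needed a rotation above 90 degrees *and* still failed its distance
    gate — the signature of feeding an unmirrored left leg.
    """
    seg_def = seg_def or SegmentDefinition()
    reg_params = reg_params or RegistrationParams()

    right = pair.right_merged()
    left = pair.left_merged()
    if mirror_plane_x is None:
        xs = np.concatenate([right.vertices[:, 0], left.vertices[:, 0]])
        mirror_plane_x = 0.5 * (xs.min() + xs.max())
    mirrored = mirror_mesh(left, mirror_plane_x)

    # coarse whole-leg pre-alignment so both legs are cut along one axis with
    # one proximal/distal orientation decision, made on the clean right leg;
    # cutting each leg by its own axis is fragile when a deformity tilts it
    t_pre = initial_align(mirrored, right, seed=reg_params.seed)
    pre = t_pre.apply_mesh(mirrored)
    u = _long_axis(right)
    r_prox, r_dist = split_segments(right, seg_def, axis=u)
    m_prox, m_dist = split_segments(pre, seg_def, axis=u)

    t_fine, prox_fit = icp_register(m_prox, r_prox, reg_params, initial="auto")
    t_prox = t_fine.compose(t_pre)
    if t_prox.rotation_angle_deg() > 90.0 and not prox_fit.passed_gate:
        raise OrientationError(
            f"subject {pair.subject!r}: proximal registration needed "
            f"{t_prox.rotation_angle_deg():.0f} deg and failed the "
            f"{prox_fit.fit_threshold} mm gate — left leg probably not mirrored"
        )

    aligned_dist = t_fine.apply_mesh(m_dist)
    dist_params = dataclasses.replace(reg_params, seed=reg_params.seed + 1)
    # the distal segments are near-aligned already, but a centroid/principal-axis
    # start is still used: a pure axial shift slides a near-tubular surface along
    # itself, and an identity start can strand ICP in that shallow valley
    t_res, dist_fit = icp_register(aligned_dist, r_dist, dist_params, initial="auto")

    angles: EulerAngles = euler_angles(t_res)
    com = center_of_mass(aligned_dist, n=com_points, seed=np.random.default_rng([reg_params.seed, 5]))
    delta = t_res.apply(com) - com

    reliable = (
        prox_fit.passed_gate
        and dist_fit.passed_gate
        and prox_fit.converged
        and dist_fit.converged
        and not angles.gimbal_lock
    )
    return DeformityReport(
        comX=float(delta[0]),
        comY=float(delta[1]),
        comZ=float(delta[2]),
        rotX=angles.rotX,
        rotY=angles.rotY,
        rotZ=angles.rotZ,
        proximal_fit=prox_fit,
        distal_fit=dist_fit,
        subject=pair.subject,
        reliable=reliable,
        gimbal_lock=angles.gimbal_lock,
    )


def batch_analyze(
    pairs,
    seg_def: SegmentDefinition | None = None,
    reg_params: RegistrationParams | None = None,
    **kwargs,
) -> tuple:
    """Analyze a cohort; returns ``(cohort DataFrame, failures dict)``.

    One row per subject in the exact cohort schema; a subject whose
    analysis raises is recorded in ``failures`` without aborting the rest.
    Raises :class:`CTMAError` only if every subject failed.
    """
    pairs = list(pairs)
    if not pairs:
        raise CTMAError("batch_analyze: empty list of leg pairs")
    rows, failures = [], {}
    base = reg_params or RegistrationParams()
    for i, pair in enumerate(pairs):
        params = dataclasses.replace(base, seed=base.seed + 1000 * i)
        try:
            rep = analyze_pair(pair, seg_def=seg_def, reg_params=params, **kwargs)
        except Exception as exc:  # per-subject fault isolation
            failures[pair.subject or str(i)] = f"{type(exc).__name__}: {exc}"
            continue
        d = rep.to_dict()
        rows.append({k: d[k] for k in COHORT_COLUMNS})
    if not rows:
        raise CTMAError(f"all {len(pairs)} subjects failed: {failures}")
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return table, failures
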