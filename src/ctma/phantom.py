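"""Parametric lower-leg phantoms with known injected deformities.

The phantom is deliberately minimal anatomy: the tibia is a tapered,
slightly waisted *elliptical* tube whose cross-section twists a little
along the shaft (so torsion is observable on the diaphysis, as it is on a
real tibia), capped by a plateau bulb proximally and a plafond bulb plus a
medial malleolus distally; the fibula is a slender tube with a head and a
lateral malleolus, offset laterally.  The left leg is generated as the
exact mirror of the right *before* any deformity is injected, so an
undeformed noiseless pair is perfectly mirror-symmetric — the fundamental
null case of the whole technique.

Deformities are injected by rigidly transforming the vertices of a
proximal or distal band of the left leg (sharp cut, or blended over a
transition band); surface noise is an independent normal displacement
along vertex normals.  Everything is seed-deterministic.

The module also ships the per-subject cohort fixture used by the
statistics layer, with a load-time self-check against its published
column means.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
import trimesh

from .errors import CTMAError, FixtureError, MeshValidationError
from .geometry import (
    RigidTransform,
    TriangleMesh,
    VoxelVolume,
    euler_angles,
    exact_surface_centroid,
    merge_meshes,
    mirror_mesh,
)
from .pipeline import LegPair, SegmentDefinition, split_segments

__all__ = [
    "DeformityInjection",
    "PhantomSpec",
    "make_leg",
    "make_pair",
    "expected_report",
    "make_cohort",
    "rasterize",
    "load_cohort_fixture",
    "FIXTURE_COLUMN_MEANS",
]

_AXES = {"X": 0, "Y": 1, "Z": 2}


@dataclasses.dataclass
class DeformityInjection:
    """A rigid deformity applied to one band of the left leg.

    ``angle_deg`` is a right-hand rotation about the given canonical axis
    through the band's own centroid, applied in the left leg's frame
    (before the analysis mirrors it back); ``translation_mm`` is added on
    top.  ``fraction`` is the Z-fraction of the leg forming the band,
    ``sharp`` cuts abruptly and ``smooth`` blends over ``band_mm``.
    """

    segment: str = "distal"  # "distal" | "proximal"
    axis: str = "Z"
    angle_deg: float = 0.0
    translation_mm: tuple = (0.0, 0.0, 0.0)
    transition: str = "sharp"  # "sharp" | "smooth"
    fraction: float = 0.4
    band_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.segment not in ("distal", "proximal"):
            raise ValueError("segment must be 'distal' or 'proximal'")
        if self.axis not in _AXES:
            raise ValueError("axis must be X, Y or Z")
        if abs(self.angle_deg) >= 90.0:
            raise ValueError("|angle| must be < 90 degrees")
        if self.transition not in ("sharp", "smooth"):
            raise ValueError("transition must be 'sharp' or 'smooth'")


@dataclasses.dataclass
class PhantomSpec:
    """Parametric description of one synthetic leg pair (all lengths mm)."""

    tibia_length: float = 350.0
    tibia_proximal_radius: float = 20.0
    tibia_distal_radius: float = 13.0
    plateau_radius: float = 28.0
    plafond_radius: float = 17.0
    malleolus_offset: float = 12.0
    fibula_length: float = 330.0
    fibula_radius: float = 6.0
    fibula_head_radius: float = 10.0
    fibula_offset: float = 34.0  # lateral shift of the fibula axis
    leg_center_x: float = 60.0  # right leg sits at +x; the left mirrors to -x
    twist_deg: float = 15.0  # cross-section twist over the shaft
    deformities: list = dataclasses.field(default_factory=list)
    noise_sd: float = 0.0
    n_theta: int = 40  # circumferential resolution
    rings_per_mm: float = 0.25  # axial resolution
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tibia_length", "tibia_proximal_radius", "tibia_distal_radius",
            "plateau_radius", "plafond_radius", "fibula_length",
            "fibula_radius", "fibula_head_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for d in self.deformities:
            if not isinstance(d, DeformityInjection):
                raise TypeError("deformities must be DeformityInjection instances")
            if d.transition == "smooth" and d.band_mm >= d.fraction * self.tibia_length:
                raise ValueError("deformity transition band exceeds the affected bone band")


# ---------------------------------------------------------------------------
# primitive surfaces


def _tube(
    z0: float,
    z1: float,
    radius_fn,
    center_fn,
    twist_fn,
    n_theta: int,
    n_z: int,
    aspect: tuple = (1.25, 0.85),
    label: str = "tube",
) -> TriangleMesh:
    """Closed elliptical tube along Z with per-level radius, centre and twist.

    Caps are concentric-ring fans so no triangle is much larger than the
    shaft quads (keeps closest-point pruning tight).
    """
    zs = np.linspace(z0, z1, n_z)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rings = []
    for z in zs:
        r = radius_fn(z)
        cx, cy = center_fn(z)
        phi = np.radians(twist_fn(z))
        a, b = r * aspect[0], r * aspect[1]
        x = a * np.cos(theta)
        y = b * np.sin(theta)
        xr = cx + x * np.cos(phi) - y * np.sin(phi)
        yr = cy + x * np.sin(phi) + y * np.cos(phi)
        rings.append(np.column_stack([xr, yr, np.full(n_theta, z)]))
    verts = [np.vstack(rings)]
    faces = []
    for i in range(n_z - 1):
        base0, base1 = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            # outward winding for CCW rings with increasing z
            faces.append([base0 + j, base0 + jn, base1 + j])
            faces.append([base0 + jn, base1 + jn, base1 + j])
    offset = n_z * n_theta

    def cap(ring_start: int, z: float, top: bool):
        nonlocal offset
        ring = verts[0][ring_start : ring_start + n_theta]
        cx, cy = center_fn(z)
        centre = np.array([cx, cy, z])
        # two concentric shrink rings, then the centre point
        shrink = [ring * s + centre * (1 - s) for s in (0.66, 0.33)]
        verts.append(np.vstack(shrink + [centre[None]]))
        ids = [np.arange(ring_start, ring_start + n_theta)]
        for k in range(2):
            ids.append(np.arange(offset + k * n_theta, offset + (k + 1) * n_theta))
        centre_id = offset + 2 * n_theta
        for a_ring, b_ring in zip(ids[:-1], ids[1:]):
            for j in range(n_theta):
                jn = (j + 1) % n_theta
                if top:
                    faces.append([a_ring[j], a_ring[jn], b_ring[j]])
                    faces.append([a_ring[jn], b_ring[jn], b_ring[j]])
                else:
                    faces.append([a_ring[jn], a_ring[j], b_ring[j]])
                    faces.append([b_ring[jn], a_ring[jn], b_ring[j]])
        inner = ids[-1]
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            if top:
                faces.append([inner[j], inner[jn], centre_id])
            else:
                faces.append([inner[jn], inner[j], centre_id])
        offset = centre_id + 1

    cap(0, zs[0], top=False)
    cap((n_z - 1) * n_theta, zs[-1], top=True)
    mesh = TriangleMesh(np.vstack(verts), np.asarray(faces), label=label)
    if mesh.signed_volume() < 0:
        mesh = mesh.flipped()
    return mesh


def _ellipsoid(center, radii, subdiv: int = 3, label: str = "bulb") -> TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=subdiv)
    v = np.asarray(s.vertices) * np.asarray(radii, float) + np.asarray(center, float)
    return TriangleMesh(v, np.asarray(s.faces), label=label)


# ---------------------------------------------------------------------------
# leg construction


def _right_leg_components(spec: PhantomSpec) -> dict:
    """Component meshes of a clean right leg (each closed), keyed by bone."""
    L = spec.tibia_length
    cx = spec.leg_center_x
    rings = max(8, int(round(L * spec.rings_per_mm)))

    def tibia_radius(z):
        s = z / L
        taper = spec.tibia_distal_radius + (spec.tibia_proximal_radius - spec.tibia_distal_radius) * s
        return taper * (1.0 - 0.15 * np.sin(np.pi * s))  # mid-shaft waist

    def tibia_center(z):
        s = z / L
        return cx + 2.0 * np.sin(np.pi * s), 1.5 * np.cos(2 * np.pi * s)  # gentle bow

    tibia = [
        _tube(0.0, L, tibia_radius, tibia_center,
              lambda z: spec.twist_deg * z / L, spec.n_theta, rings, label="tibia shaft"),
        _ellipsoid([cx, 0.0, L - 6.0],
                   [spec.plateau_radius, spec.plateau_radius * 0.8, 11.0], label="plateau"),
        _ellipsoid([cx, 0.0, 7.0],
                   [spec.plafond_radius, spec.plafond_radius * 0.9, 9.0], label="plafond"),
        _ellipsoid([cx - spec.malleolus_offset, 3.0, 2.0],
                   [7.0, 6.0, 8.0], subdiv=2, label="medial malleolus"),
    ]
    fl = spec.fibula_length
    f_lo = 4.0
    fib_rings = max(8, int(round(fl * spec.rings_per_mm)))

    def fib_center(z):
        s = (z - f_lo) / fl
        return cx + spec.fibula_offset - 3.0 * np.sin(np.pi * s), 6.0 * (s - 0.5)

    fibula = [
        _tube(f_lo, f_lo + fl, lambda z: spec.fibula_radius, fib_center,
              lambda z: 0.0, max(18, spec.n_theta // 2), fib_rings,
              aspect=(1.1, 0.9), label="fibula shaft"),
        _ellipsoid([cx + spec.fibula_offset, 2.5, f_lo + fl - 4.0],
                   [spec.fibula_head_radius] * 2 + [spec.fibula_head_radius * 1.2],
                   subdiv=2, label="fibular head"),
        _ellipsoid([cx + spec.fibula_offset + 2.0, -2.0, f_lo + 2.0],
                   [6.0, 5.0, 9.0], subdiv=2, label="lateral malleolus"),
    ]
    return {"tibia": tibia, "fibula": fibula}


def _injection_transform(inj: DeformityInjection, pivot: np.ndarray) -> RigidTransform:
    """The injected rigid motion as a transform about the given pivot."""
    a = np.radians(inj.angle_deg)
    c, s = np.cos(a), np.sin(a)
    r = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][_AXES[inj.axis]]
    r[i, i] = c
    r[j, j] = c
    r[i, j] = -s
    r[j, i] = s
    u = np.asarray(inj.translation_mm, float)
    return RigidTransform(r, pivot - r @ pivot + u)


def _injection_weights(z: np.ndarray, inj: DeformityInjection, z_lo: float, z_hi: float) -> np.ndarray:
    L = z_hi - z_lo
    if inj.segment == "distal":
        z_cut = z_lo + inj.fraction * L
        x = (z_cut - z) / max(inj.band_mm, 1e-9)
    else:
        z_cut = z_hi - inj.fraction * L
        x = (z - z_cut) / max(inj.band_mm, 1e-9)
    if inj.transition == "sharp":
        return (x >= 0).astype(float)
    t = np.clip(x + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)  # smoothstep over the band


def _band_pivot(all_verts: np.ndarray, inj: DeformityInjection, z_lo: float, z_hi: float) -> np.ndarray:
    w = _injection_weights(all_verts[:, 2], inj, z_lo, z_hi)
    sel = all_verts[w >= 0.999]
    if len(sel) == 0:
        raise CTMAError("deformity band contains no vertices")
    return sel.mean(axis=0)


def make_leg(spec: PhantomSpec, side: str, merged: bool = True):
    """Generate one leg; returns ``{bone: mesh}`` (or ``{bone: [components]}``).

    The right leg is the clean reference.  The left leg is its exact
    mirror about the plane ``x = 0``, after which the spec's deformity
    injections (left-frame rigid motions of a proximal or distal band) and
    then surface noise are applied.  The right leg receives noise only
    (independent draw).  Deterministic for a fixed spec seed.
    """
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    comps = _right_leg_components(spec)
    if side == "left":
        comps = {bone: [mirror_mesh(m, 0.0) for m in parts] for bone, parts in comps.items()}
        if spec.deformities:
            all_v = np.vstack([m.vertices for parts in comps.values() for m in parts])
            z_lo, z_hi = all_v[:, 2].min(), all_v[:, 2].max()
            # band weights are defined on the undeformed geometry, so stacking
            # several injections composes their rigid motions on a fixed band
            orig = {id(m): m.vertices.copy() for parts in comps.values() for m in parts}
            for inj in spec.deformities:
                pivot = _band_pivot(all_v, inj, z_lo, z_hi)
                t = _injection_transform(inj, pivot)
                for parts in comps.values():
                    for m in parts:
                        w = _injection_weights(orig[id(m)][:, 2], inj, z_lo, z_hi)
                        moved = t.apply(m.vertices)
                        m.vertices = m.vertices + w[:, None] * (moved - m.vertices)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 17 if side == "right" else 19])
        for parts in comps.values():
            for m in parts:
                normals = np.asarray(m.as_trimesh().vertex_normals)
                m.vertices = m.vertices + rng.normal(0.0, spec.noise_sd, len(m.vertices))[:, None] * normals
    if not merged:
        return comps
    return {
        bone: merge_meshes(parts, label=f"{side} {bone}") for bone, parts in comps.items()
    }


def make_pair(spec: PhantomSpec, subject: str = "phantom") -> LegPair:
    return LegPair(
        right=make_leg(spec, "right"),
        left=make_leg(spec, "left"),
        subject=subject,
    )


# ---------------------------------------------------------------------------
# ground truth for recovery tests


def expected_report(spec: PhantomSpec, seg_def: SegmentDefinition | None = None) -> dict:
    """The six parameter values the analysis should recover for this spec.

    Derivation: the analysis mirrors the left leg back, so the injected
    left-frame motion ``A`` appears as its sagittal-mirror conjugate
    ``D = M A M``; after proximal alignment the distal registration
    recovers ``T = D^{-1}``, whose clinical Euler angles are the rotation
    truth, and the centre-of-mass displacement is ``c0 - D(c0)`` with
    ``c0`` the clean right distal-segment centroid.  Exact for sharp
    single-band distal injections that fully contain the analysis segment.
    """
    seg_def = seg_def or SegmentDefinition()
    clean = dataclasses.replace(spec, deformities=[], noise_sd=0.0)
    comps = _right_leg_components(clean)
    right = merge_meshes([m for parts in comps.values() for m in parts], label="right")
    _, r_dist = split_segments(right, seg_def)
    c0 = exact_surface_centroid(r_dist)

    all_v = np.vstack([mirror_mesh(m, 0.0).vertices for parts in comps.values() for m in parts])
    z_lo, z_hi = all_v[:, 2].min(), all_v[:, 2].max()

    m4 = np.diag([-1.0, 1.0, 1.0, 1.0])  # generator mirror plane is x = 0
    a4 = np.eye(4)
    for inj in spec.deformities:
        t = _injection_transform(inj, _band_pivot(all_v, inj, z_lo, z_hi))
        a4 = t.to_matrix() @ a4
    d = RigidTransform.from_matrix(m4 @ a4 @ m4)
    t_res = d.invert()
    ang = euler_angles(t_res)
    delta = c0 - d.apply(c0)
    return {
        "COMX_mm": float(delta[0]),
        "COMY_mm": float(delta[1]),
        "COMZ_mm": float(delta[2]),
        "ROTX_deg": ang.rotX,
        "ROTY_deg": ang.rotY,
        "ROTZ_deg": ang.rotZ,
    }


def make_cohort(
    n_subjects: int,
    rot_sd_deg: float = 1.5,
    trans_sd_mm: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> tuple:
    """Generate ``n_subjects`` leg pairs with random distal deformities.

    Per subject, each rotation axis gets an independent ``N(0, rot_sd)``
    degree injection and the translation vector is ``N(0, trans_sd)`` per
    axis — magnitudes of the order reported for healthy side-to-side
    asymmetry.  Returns ``(pairs, truth DataFrame)`` where the truth table
    holds the values :func:`analyze_pair` should report.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng([seed, 23])
    base = base_spec or PhantomSpec()
    pairs, rows = [], []
    for i in range(n_subjects):
        angles = rng.normal(0.0, rot_sd_deg, 3) if rot_sd_deg > 0 else np.zeros(3)
        trans = rng.normal(0.0, trans_sd_mm, 3) if trans_sd_mm > 0 else np.zeros(3)
        defs = [
            DeformityInjection(segment="distal", axis=ax, angle_deg=float(a))
            for ax, a in zip("XYZ", angles)
        ]
        defs.append(DeformityInjection(segment="distal", axis="Z", angle_deg=0.0,
                                       translation_mm=tuple(trans)))
        sp = dataclasses.replace(
            base, deformities=defs, noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1))
        )
        subject = f"S{i + 1:02d}"
        pairs.append(make_pair(sp, subject=subject))
        truth = expected_report(sp)
        truth["subject"] = subject
        rows.append(truth)
    truth_table = pd.DataFrame(rows)[
        ["subject", "COMX_mm", "COMY_mm", "COMZ_mm", "ROTX_deg", "ROTY_deg", "ROTZ_deg"]
    ]
    return pairs, truth_table


# ---------------------------------------------------------------------------
# HU rasterization (to exercise the segmentation layer)


def rasterize(
    components,
    spacing: float = 1.0,
    hu_bone: float = 1200.0,
    hu_soft: float = 40.0,
    hu_air: float = -1000.0,
    margin_mm: float = 8.0,
    soft_hull: bool = True,
) -> VoxelVolume:
    """Voxelize closed bone surfaces into a Hounsfield volume.

    ``components`` is a flat list of *closed* meshes (overlapping parts of
    one bone are fine: the inside test is per component, OR-ed).  Interior
    voxels get ``hu_bone``; a convex soft-tissue hull (the bone hull pushed
    out ~8 mm) gets ``hu_soft``; the rest is ``hu_air``.  Inside tests use
    vertical ray-crossing parity per voxel column.
    """
    comps = list(components)
    if not comps:
        bounds = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    else:
        for m in comps:
            tm = m.as_trimesh()
            if not tm.is_watertight:
                raise MeshValidationError(f"component {m.label!r} is not closed; cannot voxelize")
        bounds = np.vstack(
            [
                np.vstack([m.bounds()[0] for m in comps]).min(axis=0),
                np.vstack([m.bounds()[1] for m in comps]).max(axis=0),
            ]
        )
    origin = bounds[0] - margin_mm
    extent = bounds[1] + margin_mm - origin
    spacing3 = np.full(3, float(spacing))
    shape = np.maximum(np.ceil(extent / spacing3).astype(int) + 1, 1)
    hu = np.full(tuple(shape), hu_air, dtype=np.float32)

    if comps:
        if soft_hull:
            merged = merge_meshes(comps, label="bones")
            hull = merged.as_trimesh().convex_hull
            hc = np.asarray(hull.vertices).mean(axis=0)
            hv = np.asarray(hull.vertices)
            pushed = hc + (hv - hc) * (1.0 + (margin_mm * 0.75) / np.linalg.norm(hv - hc, axis=1))[:, None]
            hull_mesh = TriangleMesh(pushed, np.asarray(hull.faces), "soft hull")
            hu[_inside_mask(hull_mesh, origin, spacing3, shape)] = hu_soft
        inside = np.zeros(tuple(shape), bool)
        for m in comps:
            inside |= _inside_mask(m, origin, spacing3, shape)
        hu[inside] = hu_bone
    return VoxelVolume(hu=hu, spacing=spacing3, origin=origin)


def _inside_mask(mesh: TriangleMesh, origin, spacing, shape) -> np.ndarray:
    """Point-in-mesh per voxel centre by z-ray crossing parity."""
    nx, ny, nz = shape
    # jitter columns off lattice-aligned geometry so rays never graze edges
    xs = origin[0] + (np.arange(nx) + 1.234e-4) * spacing[0]
    ys = origin[1] + (np.arange(ny) + 2.468e-4) * spacing[1]
    zc = origin[2] + np.arange(nz) * spacing[2]

    tri = mesh.triangles()
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # bucket triangles by the x-columns their projection can touch
    txmin, txmax = tri[..., 0].min(axis=1), tri[..., 0].max(axis=1)
    ix0 = np.clip(np.searchsorted(xs, txmin, "left"), 0, nx)
    ix1 = np.clip(np.searchsorted(xs, txmax, "right"), 0, nx)
    buckets: list = [[] for _ in range(nx)]
    for t_idx in range(len(tri)):
        for ix in range(ix0[t_idx], ix1[t_idx]):
            buckets[ix].append(t_idx)

    mask = np.zeros((nx, ny, nz), bool)
    for ix in range(nx):
        if not buckets[ix]:
            continue
        t_sel = np.asarray(buckets[ix])
        ta, tb, tc = a[t_sel], b[t_sel], c[t_sel]
        x = xs[ix]
        tymin = np.minimum.reduce([ta[:, 1], tb[:, 1], tc[:, 1]])
        tymax = np.maximum.reduce([ta[:, 1], tb[:, 1], tc[:, 1]])
        iy0 = np.clip(np.searchsorted(ys, tymin, "left"), 0, ny)
        iy1 = np.clip(np.searchsorted(ys, tymax, "right"), 0, ny)
        for iy in range(ny):
            cand = t_sel[(iy0 <= iy) & (iy < iy1)]
            if len(cand) == 0:
                continue
            z_hits = _column_hits(a[cand], b[cand], c[cand], x, ys[iy])
            if len(z_hits) < 2:
                continue
            z_hits.sort()
            for z_in, z_out in zip(z_hits[0::2], z_hits[1::2]):
                k0 = int(np.searchsorted(zc, z_in, "left"))
                k1 = int(np.searchsorted(zc, z_out, "right"))
                mask[ix, iy, k0:k1] = True
    return mask


def _column_hits(a, b, c, x: float, y: float) -> np.ndarray:
    """Z-values where the vertical line (x, y) crosses the given triangles."""
    p = np.array([x, y])
    e1 = (b - a)[:, :2]
    e2 = (c - a)[:, :2]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    ok = np.abs(det) > 1e-12
    if not ok.any():
        return np.empty(0)
    ap = p - a[:, :2]
    u = (ap[:, 0] * e2[:, 1] - ap[:, 1] * e2[:, 0]) / np.where(ok, det, 1.0)
    v = (e1[:, 0] * ap[:, 1] - e1[:, 1] * ap[:, 0]) / np.where(ok, det, 1.0)
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
    if not hit.any():
        return np.empty(0)
    z = a[hit, 2] + u[hit] * (b[hit, 2] - a[hit, 2]) + v[hit] * (c[hit, 2] - a[hit, 2])
    return z


# ---------------------------------------------------------------------------
# the published per-subject cohort fixture

# printed column means the packaged fixture must reproduce (self-check)
FIXTURE_COLUMN_MEANS = {
    "COMX_mm": -1.626,
    "COMY_mm": -0.739,
    "COMZ_mm": 0.910,
    "ROTX_deg": -0.264,
    "ROTY_deg": 0.703,
    "ROTZ_deg": -1.184,
}


def load_cohort_fixture() -> pd.DataFrame:
    """The packaged 10-subject, six-parameter cohort table.

    The loader recomputes every column mean and refuses to return a table
    that strays more than 0.01 from the published means (corrupt
    packaging guard; the ROTZ mean is only reproducible to ~0.005 from the
    rounded per-subject values).
    """
    with resources.files("ctma.data").joinpath("cohort_table.csv").open() as fh:
        table = pd.read_csv(fh)
    expected_cols = ["subject"] + list(FIXTURE_COLUMN_MEANS)
    if list(table.columns) != expected_cols or len(table) != 10:
        raise FixtureError("cohort fixture: unexpected shape or columns")
    for col, mean in FIXTURE_COLUMN_MEANS.items():
        got = table[col].mean()
        if abs(got - mean) > 0.01:
            raise FixtureError(
                f"cohort fixture self-check failed: {col} mean {got:.4f} != {mean:.3f} +/- 0.01"
            )
    return table
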