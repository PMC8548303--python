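"""Seeded Hounsfield-threshold bone segmentation and isosurfacing.

The clinical workflow is a click inside each bone of interest plus an
intensity rule: here that is 26-connected region growing over voxels at or
above a Hounsfield threshold (default 250 HU, bracketing cortical and
dense trabecular bone).  Where one thresholded region contains seeds with
different labels, voxels are assigned to the nearest seed in millimetres
(ties to the lexicographically lower label), so the label masks are always
pairwise disjoint.  This is a documented stand-in for the proprietary
two-parameter segmentation of the commercial software; downstream accuracy
is established by round-trip tests, not by algorithmic equivalence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import SegmentationError
from .geometry import TriangleMesh, VoxelVolume

__all__ = ["SeedClick", "BoneMask", "segment_bone", "mask_to_mesh"]

DEFAULT_HU_THRESHOLD = 250.0


@dataclasses.dataclass
class SeedClick:
    """A user click: a position (mm, canonical frame) inside the bone to segment."""

    position: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)


@dataclasses.dataclass
class BoneMask:
    """Binary voxel mask aligned to its source volume."""

    mask: np.ndarray
    label: str
    touches_border: bool = False  # possible truncation of the bone by the FOV

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _seed_index(volume: VoxelVolume, seed: SeedClick) -> tuple:
    idx = np.rint(volume.world_to_index(seed.position)).astype(int)
    if (idx < 0).any() or (idx >= np.array(volume.shape)).any():
        raise SegmentationError(f"seed {seed.label!r} at {seed.position} lies outside the volume")
    return tuple(idx)


def segment_bone(
    volume: VoxelVolume,
    seeds,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    majority_filter: bool = False,
) -> dict:
    """Grow one mask per seed label; returns ``{label: BoneMask}``.

    Raises :class:`SegmentationError` naming the seed if its voxel falls
    below the threshold.  Masks whose region touches the volume border are
    flagged ``touches_border`` (the bone may be cut by the field of view).
    """
    seeds = list(seeds)
    if not seeds:
        raise SegmentationError("no seeds given")
    above = volume.hu >= hu_threshold
    if majority_filter:
        counts = ndimage.convolve(above.astype(np.uint8), np.ones((3, 3, 3), np.uint8), mode="constant")
        above = counts >= 14
    comp, _ = ndimage.label(above, structure=np.ones((3, 3, 3), bool))

    seed_idx = {}
    for s in seeds:
        idx = _seed_index(volume, s)
        if volume.hu[idx] < hu_threshold:
            raise SegmentationError(
                f"seed {s.label!r} at {s.position} has HU {volume.hu[idx]:.0f} "
                f"below threshold {hu_threshold:.0f}"
            )
        if comp[idx] == 0:
            raise SegmentationError(f"seed {s.label!r}: no thresholded region at the seed (filtered away)")
        seed_idx.setdefault(s.label, []).append((idx, s.position))

    # group seeds by connected component
    comp_labels: dict = {}
    for label, entries in seed_idx.items():
        for idx, pos in entries:
            comp_labels.setdefault(comp[idx], set()).add(label)

    labels_sorted = sorted(seed_idx)  # lexicographic order = tie-break priority
    masks = {lab: np.zeros(volume.shape, bool) for lab in labels_sorted}
    for cid, labs in comp_labels.items():
        region = comp == cid
        labs = sorted(labs)
        if len(labs) == 1:
            masks[labs[0]] |= region
            continue
        # shared region: nearest-seed partition in millimetres
        vox = np.argwhere(region)
        world = volume.origin + vox * volume.spacing
        dists = np.full((len(labs), len(vox)), np.inf)
        for li, lab in enumerate(labs):
            for idx, pos in seed_idx[lab]:
                if comp[idx] != cid:
                    continue
                dists[li] = np.minimum(dists[li], np.linalg.norm(world - pos, axis=1))
        winner = dists.argmin(axis=0)  # argmin takes the first (lexicographically lower) label on ties
        for li, lab in enumerate(labs):
            sel = vox[winner == li]
            masks[lab][sel[:, 0], sel[:, 1], sel[:, 2]] = True

    out = {}
    for lab in labels_sorted:
        m = masks[lab]
        if not m.any():
            raise SegmentationError(f"label {lab!r}: empty region")
        border = (
            m[0].any() or m[-1].any()
            or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()
        )
        out[lab] = BoneMask(mask=m, label=lab, touches_border=bool(border))
    return out


def mask_to_mesh(mask: BoneMask, volume: VoxelVolume) -> TriangleMesh:
    """Marching-cubes isosurface of a mask, in world millimetres.

    The mask is zero-padded so surfaces at the volume border close; the
    output winding is fixed to give positive signed volume.
    """
    if not mask.mask.any():
        raise SegmentationError(f"label {mask.label!r}: cannot mesh an empty mask")
    padded = np.pad(mask.mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(volume.spacing))
    verts = verts - volume.spacing + volume.origin  # undo the one-voxel pad
    mesh = TriangleMesh(verts, faces, label=mask.label)
    if mesh.signed_volume() < 0:
        mesh = mesh.flipped()
    return mesh
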