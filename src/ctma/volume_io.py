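"""Loaders that bring CT volumes into the canonical patient frame.

The canonical frame has X running left→right, Y front→back (anterior→
posterior) and Z feet→head.  DICOM patient coordinates (LPS: +X toward
the patient's *left*) therefore need their X axis negated; NIfTI RAS
coordinates need Y negated.  Note the source convention mismatch is real:
DICOM's own X axis points the opposite way from the left→right axis this
package (and the clinical varus/valgus reading) is defined in, so the
flip is applied explicitly and tagged on the volume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import CTMAError
from .geometry import VoxelVolume


def load_nifti(path, to_canonical: bool = True) -> VoxelVolume:
    """Load a NIfTI volume (axis-aligned affines only)."""
    import nibabel as nib

    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS+
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise CTMAError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3].copy()
    if to_canonical:
        # RAS -> canonical: negate Y (anterior -> front-to-back)
        data = data[:, ::-1, :].copy()
        origin[1] = -(origin[1] + spacing[1] * (data.shape[1] - 1))
    return VoxelVolume(hu=data, spacing=spacing, origin=origin,
                       axes="canonical" if to_canonical else "RAS")


def load_dicom_series(directory, to_canonical: bool = True) -> VoxelVolume:
    """Load an axial DICOM series directory via SimpleITK/pydicom.

    Slices are sorted by position; gantry-tilted or non-axial acquisitions
    are rejected.  With ``to_canonical`` the LPS X axis is negated so that
    +X runs from the patient's left to the right.
    """
    import pydicom

    files = sorted(Path(directory).glob("*"))
    slices = []
    for f in files:
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise CTMAError(f"{directory}: no readable DICOM slices")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = slices[0]
    orient = np.array(first.ImageOrientationPatient, float)
    if not np.allclose(np.abs(orient), [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise CTMAError("only axial, untilted DICOM series are supported")
    px = np.array(first.PixelSpacing, float)  # (row, col) = (y, x)
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    stack = np.stack([s.pixel_array for s in slices], axis=-1).astype(np.float32)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    inter = float(getattr(first, "RescaleIntercept", 0.0))
    hu = stack * slope + inter
    hu = np.transpose(hu, (1, 0, 2))  # (row=y, col=x, z) -> (x, y, z)
    origin = np.array(first.ImagePositionPatient, float)
    spacing = np.array([px[1], px[0], abs(dz)])
    if to_canonical:
        hu = hu[::-1, :, :].copy()  # LPS +X (left) -> canonical +X (right)
        origin[0] = -(origin[0] + px[1] * (hu.shape[0] - 1))
    return VoxelVolume(hu=hu, spacing=spacing, origin=origin,
                       axes="canonical" if to_canonical else "LPS")


def save_mask_nifti(mask, volume: VoxelVolume, path) -> None:
    """Export a segmentation mask on its source grid as NIfTI."""
    import nibabel as nib

    aff = np.diag(list(volume.spacing) + [1.0])
    aff[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), aff), str(path))
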