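"""Conversions between numpy grids, NIfTI files and SimpleITK images.

Arrays are indexed (x, y, z) throughout the package; SimpleITK stores
(z, y, x), so conversions transpose. Phantom grids use an axis-aligned
affine with the origin at zero, which keeps the voxel->mm map identical
in both toolkits.
"""

from __future__ import annotations

import nibabel as nib
import numpy as np
import SimpleITK as sitk


def grid_affine(spacing_mm) -> np.ndarray:
    """Axis-aligned affine (origin 0) for a given voxel spacing."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def to_sitk(arr: np.ndarray, spacing_mm) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    return img


def from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def save_nifti(arr: np.ndarray, spacing_mm, path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr).astype(dtype), grid_affine(spacing_mm)), str(path))


def load_nifti(path):
    """Return (data, spacing_mm, affine)."""
    img = nib.load(str(path))
    return (
        np.asanyarray(img.dataobj),
        tuple(float(z) for z in img.header.get_zooms()[:3]),
        img.affine,
    )
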