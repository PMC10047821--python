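"""Reading and writing volumes: NIfTI (nibabel) and MetaImage (SimpleITK).

Arrays are exchanged in (x, y, z) axis order.  SimpleITK stores arrays as
(z, y, x); the transpose happens here so the rest of the package never sees
it.  Displacement fields round-trip as 4D volumes with a trailing axis of
size 3.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .core import DisplacementField, MaskVolume, PhaseImage

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_EXT)


def _is_meta(path: str) -> bool:
    return path.endswith(_META_EXT)


def _read_array(path: str):
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, spacing
    if _is_meta(path):
        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img)  # (z, y, x) [+ components]
        if data.ndim == 3:
            data = data.transpose(2, 1, 0)
        elif data.ndim == 4:
            data = data.transpose(2, 1, 0, 3)
        spacing = tuple(float(s) for s in img.GetSpacing()[:3])
        return data, spacing
    raise ValueError(f"unsupported volume format: {path}")


def _write_array(path: str, data: np.ndarray, spacing) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), path)
        return
    if _is_meta(path):
        if data.ndim == 3:
            img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        else:
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(data.transpose(2, 1, 0, 3)), isVector=True)
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_image(path: str, phase: str = "AP", normalized: bool = False) -> PhaseImage:
    data, spacing = _read_array(path)
    return PhaseImage(np.asarray(data, dtype=np.float64), spacing=spacing,
                      phase=phase, normalized=normalized)


def write_image(path: str, img: PhaseImage) -> None:
    _write_array(path, np.asarray(img.data, dtype=np.float32), img.spacing)


def read_mask(path: str, role: str = "liver") -> MaskVolume:
    data, spacing = _read_array(path)
    return MaskVolume((np.asarray(data) > 0.5).astype(np.uint8), spacing=spacing, role=role)


def write_mask(path: str, mask: MaskVolume) -> None:
    _write_array(path, mask.data.astype(np.uint8), mask.spacing)


def read_field(path: str) -> DisplacementField:
    data, _ = _read_array(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"displacement field must be 4D with last axis 3, got {data.shape}")
    return DisplacementField(np.moveaxis(np.asarray(data, dtype=np.float64), -1, 0))


def write_field(path: str, field: DisplacementField, spacing=(1.0, 1.0, 1.0)) -> None:
    _write_array(path, np.moveaxis(field.u, 0, -1).astype(np.float32), spacing)
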