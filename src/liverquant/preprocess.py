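"""Deterministic study preparation before nonlinear registration.

Order of operations mirrors the clinical workflow: resample to isotropic
spacing, crop to the liver bounding box, normalize intensities to [0, 1]
with a display window, rigid pre-alignment of each moving phase to the
arterial phase by maximizing normalized correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import MaskVolume, PhaseImage, Study


@dataclass
class WindowSpec:
    """Intensity display window (center/width), Hounsfield-like units."""

    center: float = 60.0
    width: float = 400.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")


@dataclass
class RigidTransform:
    """Pure rigid transform: 3 Euler angles (radians) + translation (mm).

    Convention: a point x (voxel coordinates, about the volume center c) in
    the *fixed* grid samples the moving image at ``R(x - c) + c + t``.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        ax, ay, az = self.rotation
        rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
        rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        return rz @ ry @ rx

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (max(abs(a) for a in self.rotation) < tol
                and max(abs(t) for t in self.translation) < tol)


def normalize_window(img: PhaseImage, w: WindowSpec) -> PhaseImage:
    """Map intensities to [0, 1]: clip((in - (c - w/2)) / w, 0, 1)."""
    lo = w.center - w.width / 2.0
    out = np.clip((np.asarray(img.data, dtype=np.float64) - lo) / w.width, 0.0, 1.0)
    return img.copy_with(out, normalized=True)


def _resample_grid(shape, spacing, target):
    """New shape preserving physical extent: extent = n * s."""
    return tuple(max(1, int(round(n * s / t))) for n, s, t in zip(shape, spacing, target))


def resample_volume(data: np.ndarray, spacing, target, order: int) -> np.ndarray:
    new_shape = _resample_grid(data.shape, spacing, target)
    if new_shape == tuple(data.shape):
        return np.array(data, copy=True)
    # sample the old grid at the new voxel centers (same physical origin at
    # voxel center 0)
    coords = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, spacing)],
        indexing="ij")
    out = ndimage.map_coordinates(data.astype(np.float64), np.stack(coords).reshape(3, -1),
                                  order=order, mode="nearest")
    return out.reshape(new_shape)


def resample_isotropic(img: PhaseImage, target_spacing=(1.0, 1.0, 1.0)) -> PhaseImage:
    """Trilinear resampling of an image to the target spacing."""
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    out = resample_volume(np.asarray(img.data, dtype=np.float64), img.spacing, target, order=1)
    return img.copy_with(out.astype(img.data.dtype, copy=False), spacing=target)


def resample_mask(mask: MaskVolume, target_spacing=(1.0, 1.0, 1.0)) -> MaskVolume:
    """Nearest-neighbor resampling for label volumes."""
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    out = resample_volume(mask.data, mask.spacing, target, order=0)
    return MaskVolume(out.astype(np.uint8), spacing=target, role=mask.role)


def liver_bbox(study: Study, margin: int = 10):
    """Union bounding box of the liver masks across phases, dilated by
    ``margin`` voxels and clipped to the grid.  Returns slices per axis."""
    shape = study.common_grid()
    union = np.zeros(shape, dtype=bool)
    for m in study.liver_masks.values():
        union |= m.astype_bool()
    if not union.any():
        raise ValueError("empty liver masks: cannot crop")
    slices = []
    for ax in range(3):
        proj = union.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        lo = max(0, idx[0] - margin)
        hi = min(shape[ax], idx[-1] + 1 + margin)
        slices.append(slice(lo, hi))
    return tuple(slices)


def crop_to_liver(study: Study, margin: int = 10) -> Study:
    """Crop every member of the study to the union liver bounding box."""
    sl = liver_bbox(study, margin)

    def _crop_img(img: PhaseImage) -> PhaseImage:
        return img.copy_with(img.data[sl])

    def _crop_masks(masks: dict) -> dict:
        return {ph: MaskVolume(m.data[sl], spacing=m.spacing, role=m.role)
                for ph, m in masks.items()}

    return Study(pre=_crop_img(study.pre), ap=_crop_img(study.ap), dp=_crop_img(study.dp),
                 liver_masks=_crop_masks(study.liver_masks),
                 lesion_masks=_crop_masks(study.lesion_masks))


# ---------------------------------------------------------------------------
# Rigid pre-alignment (normalized correlation metric)
# ---------------------------------------------------------------------------

def ncc(a: np.ndarray, b: np.ndarray, weight: np.ndarray | None = None) -> float:
    """Normalized correlation coefficient, optionally restricted to a
    boolean region of interest."""
    if weight is not None:
        a = a[weight]
        b = b[weight]
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom < 1e-12:
        return 0.0
    return float((a @ b) / denom)


def apply_rigid(data: np.ndarray, transform: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample ``data`` under the rigid transform (about the volume center).

    Backward mapping: output(x) = data(R(x - c) + c + t).
    """
    if transform.is_identity():
        return np.array(data, copy=True)
    center = (np.array(data.shape, dtype=np.float64) - 1.0) / 2.0
    rot = transform.matrix()
    offset = center + np.asarray(transform.translation) - rot @ center
    return ndimage.affine_transform(data.astype(np.float64), rot, offset=offset,
                                    order=order, mode="nearest")


def _downsample2(data: np.ndarray) -> np.ndarray:
    return ndimage.zoom(ndimage.gaussian_filter(data, 0.8),
                        0.5, order=1, mode="nearest", grid_mode=False)


def rigid_prealign(fixed: PhaseImage, moving: PhaseImage,
                   max_rotation: float = 0.35,
                   weight: np.ndarray | None = None) -> tuple[RigidTransform, PhaseImage]:
    """Rigid transform maximizing NCC between fixed and resampled moving.

    Powell optimization on a half-resolution pair (the NCC optimum
    transfers to full resolution well below the voxel scale).  ``weight``
    optionally restricts the metric to a boolean region (e.g. the liver),
    so the transform aligns the organ of interest rather than whatever
    dominates the field of view.  The achieved correlation never falls
    below the identity-transform correlation (identity fallback).
    Degenerate (constant) inputs return the identity with a warning.
    """
    if fixed.shape != moving.shape:
        raise ValueError("rigid_prealign expects both images on one grid")
    fdat = np.asarray(fixed.data, dtype=np.float64)
    mdat = np.asarray(moving.data, dtype=np.float64)
    if fdat.std() < 1e-12 or mdat.std() < 1e-12:
        warnings.warn("degenerate (constant) image: rigid pre-alignment skipped")
        return RigidTransform(), moving.copy_with(np.array(mdat, copy=True))

    def objective(params, f, m, w, scale):
        t = RigidTransform(rotation=tuple(params[:3]),
                           translation=tuple(np.asarray(params[3:]) * scale))
        return -ncc(f, apply_rigid(m, t), w)

    f2, m2 = _downsample2(fdat), _downsample2(mdat)
    w2 = None
    if weight is not None:
        w2 = ndimage.zoom(weight.astype(np.float64), 0.5, order=1,
                          mode="nearest", grid_mode=False) > 0.25
    x0 = np.zeros(6)
    res = optimize.minimize(objective, x0, args=(f2, m2, w2, 0.5), method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 40})
    params = np.asarray(res.x, dtype=np.float64)
    params[:3] = np.clip(params[:3], -max_rotation, max_rotation)
    transform = RigidTransform(rotation=tuple(params[:3]), translation=tuple(params[3:]))
    aligned = apply_rigid(mdat, transform)
    if ncc(fdat, aligned, weight) < ncc(fdat, mdat, weight):
        transform = RigidTransform()
        aligned = np.array(mdat, copy=True)
    return transform, moving.copy_with(aligned)


def preprocess_study(study: Study, window: WindowSpec | None = None,
                     target_spacing=(1.0, 1.0, 1.0), margin: int = 10,
                     rigid: bool = True) -> tuple[Study, dict]:
    """Full preprocessing chain; returns the prepared study and provenance.

    Moving phases (Pre, DP) are rigidly pre-aligned to AP inside the cropped
    liver bounding box; their masks are resampled with the same transform
    (nearest-neighbor).
    """
    window = window or WindowSpec()
    imgs = {ph: resample_isotropic(img, target_spacing) for ph, img in study.phases().items()}
    livers = {ph: resample_mask(m, target_spacing) for ph, m in study.liver_masks.items()}
    lesions = {ph: resample_mask(m, target_spacing) for ph, m in study.lesion_masks.items()}
    resampled = Study(pre=imgs["Pre"], ap=imgs["AP"], dp=imgs["DP"],
                      liver_masks=livers, lesion_masks=lesions)
    cropped = crop_to_liver(resampled, margin=margin)
    normed = {ph: normalize_window(img, window) for ph, img in cropped.phases().items()}

    # restrict the rigid metric to the (dilated) union liver region so the
    # transform aligns the liver rather than the whole field of view
    union = np.zeros(normed["AP"].shape, dtype=bool)
    for m in cropped.liver_masks.values():
        union |= m.astype_bool()
    union = ndimage.binary_dilation(union, iterations=3)

    transforms: dict[str, RigidTransform] = {}
    out_livers = dict(cropped.liver_masks)
    out_lesions = dict(cropped.lesion_masks)
    for ph in ("Pre", "DP"):
        if rigid:
            t, aligned = rigid_prealign(normed["AP"], normed[ph], weight=union)
        else:
            t, aligned = RigidTransform(), normed[ph]
        transforms[ph] = t
        normed[ph] = aligned
        for masks, out in ((cropped.liver_masks, out_livers), (cropped.lesion_masks, out_lesions)):
            if ph in masks:
                warped = apply_rigid(masks[ph].data, t, order=0)
                out[ph] = MaskVolume((warped > 0.5).astype(np.uint8),
                                     spacing=masks[ph].spacing, role=masks[ph].role)

    prepared = Study(pre=normed["Pre"], ap=normed["AP"], dp=normed["DP"],
                     liver_masks=out_livers, lesion_masks=out_lesions)
    provenance = {
        "window": {"center": window.center, "width": window.width},
        "resample": {"spacing": list(target_spacing)},
        "crop": {"margin": margin},
        "rigid": {ph: {"rotation": list(t.rotation), "translation": list(t.translation)}
                  for ph, t in transforms.items()},
    }
    return prepared, provenance
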