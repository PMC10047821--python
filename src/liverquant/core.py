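"""Volumetric data model and low-level numerics.

All volumes are numpy arrays in ``(x, y, z)`` axis order with 0-based
indexing.  Displacement fields follow the backward (pull-back) warping
convention: a field ``u`` on the fixed grid deforms a moving image ``M`` as
``warped(x) = M(x + u(x))``, with ``u`` expressed in voxel units of the
moving grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

PHASES = ("Pre", "AP", "PV", "DP")
MASK_ROLES = ("liver", "lesion", "feature")


@dataclass
class PhaseImage:
    """One 3D scalar CT volume with physical spacing and a phase label.

    Intensities are dimensionless; after window normalization they live in
    [0, 1] (``normalized`` tracks whether that contract currently holds).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase: str = "AP"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray, **kw) -> "PhaseImage":
        return replace(self, data=data, **kw)


@dataclass
class MaskVolume:
    """Binary label volume (values in {0, 1}) on the same grid as its image."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    role: str = "liver"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.role not in MASK_ROLES:
            raise ValueError(f"role must be one of {MASK_ROLES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class DisplacementField:
    """Per-voxel 3-component displacement, voxel units, on the fixed grid.

    ``u`` has shape ``(3,) + grid_shape``; ``u[i]`` is the displacement along
    axis ``i``.  A zero field is the identity warp.
    """

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(f"field must have shape (3, nx, ny, nz), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]

    @classmethod
    def zeros(cls, shape: Sequence[int], dtype=np.float64) -> "DisplacementField":
        return cls(np.zeros((3, *shape), dtype=dtype))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.u.astype(np.float64) ** 2, axis=0))


@dataclass
class Study:
    """A Pre/AP/DP triplet with per-phase liver and lesion masks."""

    pre: PhaseImage
    ap: PhaseImage
    dp: PhaseImage
    liver_masks: dict = field(default_factory=dict)   # phase label -> MaskVolume
    lesion_masks: dict = field(default_factory=dict)  # phase label -> MaskVolume

    def phases(self) -> dict:
        return {"Pre": self.pre, "AP": self.ap, "DP": self.dp}

    def common_grid(self) -> tuple[int, int, int]:
        shapes = {img.shape for img in self.phases().values()}
        shapes |= {m.shape for m in self.liver_masks.values()}
        shapes |= {m.shape for m in self.lesion_masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"study members are on different grids: {shapes}")
        return next(iter(shapes))


# ---------------------------------------------------------------------------
# Sampling and warping
# ---------------------------------------------------------------------------

def _sample_corners(vol: np.ndarray, coords: np.ndarray):
    """Clamped trilinear setup: cell indices, fractions and the 8 corners.

    ``coords`` has shape (3, n).  Coordinates are clamped to the volume's
    bounding box (nearest-edge extension), so the interpolant is constant
    outside the grid.
    """
    shape = vol.shape
    c = np.empty_like(coords, dtype=np.float64)
    for ax in range(3):
        np.clip(coords[ax], 0.0, shape[ax] - 1.0, out=c[ax])
    i0 = np.empty(c.shape, dtype=np.intp)
    f = np.empty_like(c)
    for ax in range(3):
        idx = np.floor(c[ax]).astype(np.intp)
        np.clip(idx, 0, shape[ax] - 2 if shape[ax] > 1 else 0, out=idx)
        i0[ax] = idx
        f[ax] = c[ax] - idx
    x0, y0, z0 = i0
    fx, fy, fz = f
    x1 = np.minimum(x0 + 1, shape[0] - 1)
    y1 = np.minimum(y0 + 1, shape[1] - 1)
    z1 = np.minimum(z0 + 1, shape[2] - 1)
    corners = (
        vol[x0, y0, z0], vol[x1, y0, z0], vol[x0, y1, z0], vol[x1, y1, z0],
        vol[x0, y0, z1], vol[x1, y0, z1], vol[x0, y1, z1], vol[x1, y1, z1],
    )
    return corners, (fx, fy, fz)


def trilinear_sample(img: PhaseImage | np.ndarray, points) -> np.ndarray:
    """Trilinear interpolation of ``img`` at continuous voxel coordinates.

    ``points`` is array-like of shape (n, 3) or (3, n); out-of-bounds points
    use nearest-edge (clamped) extension.
    """
    vol = img.data if isinstance(img, PhaseImage) else np.asarray(img)
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[0] == 3 and pts.shape[-1] != 3:
        coords = pts
    else:
        coords = pts.T
    if not np.all(np.isfinite(coords)):
        raise ValueError("sample points must be finite")
    (c000, c100, c010, c110, c001, c101, c011, c111), (fx, fy, fz) = _sample_corners(vol, coords)
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def trilinear_sample_multi(vols, coords: np.ndarray) -> list:
    """Clamped trilinear sampling of several volumes on one grid at shared
    coordinates; the cell/weight setup is computed once."""
    vols = [np.asarray(v) for v in vols]
    shape = vols[0].shape
    c = np.empty_like(coords, dtype=np.float64)
    for ax in range(3):
        np.clip(coords[ax], 0.0, shape[ax] - 1.0, out=c[ax])
    idx0, fr = [], []
    for ax in range(3):
        idx = np.floor(c[ax]).astype(np.intp)
        np.clip(idx, 0, shape[ax] - 2 if shape[ax] > 1 else 0, out=idx)
        idx0.append(idx)
        fr.append(c[ax] - idx)
    x0, y0, z0 = idx0
    fx, fy, fz = fr
    x1 = np.minimum(x0 + 1, shape[0] - 1)
    y1 = np.minimum(y0 + 1, shape[1] - 1)
    z1 = np.minimum(z0 + 1, shape[2] - 1)
    w000 = (1 - fx) * (1 - fy) * (1 - fz)
    w100 = fx * (1 - fy) * (1 - fz)
    w010 = (1 - fx) * fy * (1 - fz)
    w110 = fx * fy * (1 - fz)
    w001 = (1 - fx) * (1 - fy) * fz
    w101 = fx * (1 - fy) * fz
    w011 = (1 - fx) * fy * fz
    w111 = fx * fy * fz
    out = []
    for v in vols:
        out.append(v[x0, y0, z0] * w000 + v[x1, y0, z0] * w100
                   + v[x0, y1, z0] * w010 + v[x1, y1, z0] * w110
                   + v[x0, y0, z1] * w001 + v[x1, y0, z1] * w101
                   + v[x0, y1, z1] * w011 + v[x1, y1, z1] * w111)
    return out


def sample_with_gradient(vol: np.ndarray, coords: np.ndarray):
    """Value and exact spatial derivative of the clamped trilinear interpolant.

    Returns ``(values, grads)`` with ``grads`` of shape (3, n).  The gradient
    is the analytic derivative of the piecewise-trilinear function (zero in
    the clamped exterior), which is what exact linearization of a warped
    image requires.
    """
    orig = coords
    (c000, c100, c010, c110, c001, c101, c011, c111), (fx, fy, fz) = _sample_corners(vol, coords)
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    val = c0 * (1 - fz) + c1 * fz

    dx = ((c100 - c000) * (1 - fy) + (c110 - c010) * fy) * (1 - fz) \
        + ((c101 - c001) * (1 - fy) + (c111 - c011) * fy) * fz
    dy = (c10 - c00) * (1 - fz) + (c11 - c01) * fz
    dz = c1 - c0
    grads = np.stack([dx, dy, dz])
    shape = vol.shape
    for ax in range(3):
        inside = (orig[ax] > 0.0) & (orig[ax] < shape[ax] - 1.0)
        grads[ax] *= inside
    return val, grads


def _warp_coords(shape, u: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    return np.stack([g + ui for g, ui in zip(grids, u)]).reshape(3, -1)


def warp_volume(vol: np.ndarray, field: DisplacementField, order: int = 1) -> np.ndarray:
    """Backward-warp ``vol`` by ``field``: out(x) = vol(x + u(x))."""
    if vol.shape != field.grid_shape:
        raise ValueError(f"volume shape {vol.shape} != field grid {field.grid_shape}")
    coords = _warp_coords(vol.shape, field.u)
    if order == 0:
        out = ndimage.map_coordinates(vol, coords, order=0, mode="nearest")
    else:
        out = trilinear_sample(vol, coords).astype(vol.dtype, copy=False)
    return out.reshape(vol.shape)


def warp_image(moving: PhaseImage, field: DisplacementField) -> PhaseImage:
    """Warp a phase image by a displacement field (trilinear, clamped edges)."""
    return moving.copy_with(warp_volume(moving.data, field, order=1))


def warp_mask(mask: MaskVolume, field: DisplacementField) -> MaskVolume:
    """Warp a binary mask by a displacement field (nearest-neighbor)."""
    return MaskVolume(warp_volume(mask.data, field, order=0),
                      spacing=mask.spacing, role=mask.role)


def image_gradient(img: PhaseImage | np.ndarray) -> np.ndarray:
    """Spatial gradient (intensity per voxel): central differences in the
    interior, one-sided at the faces.  Returns shape (3,) + vol.shape."""
    vol = img.data if isinstance(img, PhaseImage) else np.asarray(img)
    if min(vol.shape) < 2:
        raise ValueError("gradient needs at least 2 voxels per axis")
    return np.stack(np.gradient(vol.astype(np.float64), edge_order=1))


# ---------------------------------------------------------------------------
# Windowed statistics support
# ---------------------------------------------------------------------------

def window_counts(shape, radius) -> np.ndarray:
    """|omega_x|: size of the cubic window clipped to the volume bounds.

    Separable: the clipped count is an outer product of per-axis counts.
    """
    rads = _as_radius_triple(radius)
    axes = []
    for n, r in zip(shape, rads):
        idx = np.arange(n)
        cnt = np.minimum(idx + r, n - 1) - np.maximum(idx - r, 0) + 1
        axes.append(cnt.astype(np.float64))
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def _as_radius_triple(radius):
    if np.isscalar(radius):
        rads = (int(radius),) * 3
    else:
        rads = tuple(int(r) for r in radius)
    if any(r < 0 for r in rads):
        raise ValueError("window radius must be non-negative")
    return rads


def box_sum(vol: np.ndarray, radius) -> np.ndarray:
    """Windowed sum over the cubic window clipped to the volume bounds."""
    rads = _as_radius_triple(radius)
    size = tuple(2 * r + 1 for r in rads)
    full = float(np.prod(size))
    out = ndimage.uniform_filter(vol.astype(vol.dtype, copy=False), size=size,
                                 mode="constant", cval=0.0, output=np.float64
                                 if vol.dtype == np.float64 else np.float32)
    return out * full


def box_mean(vol: np.ndarray, radius) -> np.ndarray:
    """Windowed mean with exact clipped-size normalization.

    out(x) = sum of vol over the clipped window / |omega_x|.  Constants are
    exactly invariant, including at the boundary.
    """
    rads = _as_radius_triple(radius)
    if all(r == 0 for r in rads):
        return np.array(vol, copy=True)
    counts = window_counts(vol.shape, rads)
    return box_sum(vol, rads) / counts
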