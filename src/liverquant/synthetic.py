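"""Seeded digital liver phantoms with ground-truth deformation.

A phantom is an ellipsoidal "liver" containing a spherical "lesion" on a
uniform background, rendered with a one-voxel partial-volume falloff at
object boundaries.  Per-phase intensity triplets reproduce the qualitative
enhancement pattern of hepatocellular carcinoma: the lesion is isodense to
liver before contrast, hyperdense in the arterial phase and hypodense in
the delayed phase.  The arterial phase is rendered on the reference grid;
the pre-contrast and delayed phases are rendered in their own deformed
geometry obtained from independent seeded smooth random displacement
fields, so every moving phase carries a known ground-truth correspondence
back to the arterial geometry.

Ground-truth convention: the stored field g maps fixed-grid coordinates
into the deformed moving volume (backward convention, the same one the
registration engine estimates), i.e. ``moving(x + g(x)) = fixed-geometry
rendering(x)`` up to the numerical inversion tolerance.  Moving volumes are
rendered analytically at inverse-displaced coordinates, so no resampling
artifacts enter the ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (DisplacementField, MaskVolume, PhaseImage, Study,
                   trilinear_sample, trilinear_sample_multi)

log = logging.getLogger(__name__)

DEFAULT_INTENSITIES = {
    # phase: (background, liver, lesion)
    "Pre": (0.05, 0.40, 0.40),
    "AP": (0.05, 0.50, 0.65),
    "DP": (0.05, 0.55, 0.45),
}


@dataclass
class PhantomSpec:
    """Geometry, contrast, noise and deformation of one synthetic study."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    liver_center: tuple[float, float, float] = (48.0, 48.0, 48.0)
    liver_axes: tuple[float, float, float] = (34.0, 30.0, 27.0)  # semi-axes, mm
    lesion_center: tuple[float, float, float] = (53.0, 49.0, 48.0)
    lesion_radius: float = 18.0  # mm (3.6 cm diameter, the dataset's modal size class)
    intensities: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_INTENSITIES.items()})
    noise_sigma: float = 0.01
    texture_amplitude: float = 0.03  # sd of anatomical parenchymal texture
    texture_sigma: float = 2.0       # correlation length of the texture, voxels
    max_magnitude: float = 6.0       # mm, peak displacement of each moving phase
    smoothness_sigma: float = 12.0   # voxels
    sliding_plane: tuple[int, float] | None = None  # (axis, offset)
    craniocaudal_bias: float = 0.0   # mm, added along axis 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_magnitude < 0:
            raise ValueError("max_magnitude must be non-negative")
        for ph, (bg, lv, le) in self.intensities.items():
            for v in (bg, lv, le):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"intensities must be in [0,1], got {v} for {ph}")
        # lesion strictly inside the liver (with a one-radius safety check)
        rel = [(c - lc) / ax for c, lc, ax in
               zip(self.lesion_center, self.liver_center, self.liver_axes)]
        rho = float(np.sqrt(sum(r * r for r in rel)))
        margin = self.lesion_radius / min(self.liver_axes)
        if rho + margin >= 1.0:
            raise ValueError("lesion must lie strictly inside the liver")

    def expected_features(self) -> set:
        """Which features the intensity triplets imply (noise-free logic)."""
        feats = set()
        _, lv_pre, le_pre = self.intensities["Pre"]
        _, lv_ap, le_ap = self.intensities["AP"]
        _, lv_dp, le_dp = self.intensities["DP"]
        if (le_ap - le_pre) > (lv_ap - lv_pre) and le_ap > lv_ap:
            feats.add("APHE")
        if (le_ap - le_pre) > 0 and (le_dp < lv_dp or (le_dp - le_pre) < (lv_dp - lv_pre)):
            feats.add("WO")
        return feats


@dataclass
class GroundTruth:
    """True correspondence and geometry of a generated phantom."""

    fields: dict          # phase -> DisplacementField (mm == voxels at 1 mm)
    masks: dict           # "liver"/"lesion" -> {phase -> MaskVolume}
    expected_features: set


def random_smooth_field(shape, max_magnitude: float, smoothness_sigma: float,
                        sliding_plane=None, seed: int = 0,
                        craniocaudal_bias: float = 0.0) -> DisplacementField:
    """Seeded Gaussian-smoothed white-noise field, rescaled so the maximum
    voxel magnitude equals ``max_magnitude``.

    With ``sliding_plane=(axis, offset)`` the far side of the plane receives
    an independently generated field (a sliding discontinuity).  An optional
    constant cranio-caudal component models breath-hold offset.
    """
    if max_magnitude < 0:
        raise ValueError("max_magnitude must be non-negative")
    rng = np.random.default_rng(seed)

    def _one(r):
        raw = r.standard_normal((3, *shape))
        sm = np.stack([ndimage.gaussian_filter(raw[i], smoothness_sigma) for i in range(3)])
        mag = np.sqrt(np.sum(sm ** 2, axis=0)).max()
        if mag < 1e-15 or max_magnitude == 0:
            return np.zeros_like(sm)
        return sm * (max_magnitude / mag)

    u = _one(rng)
    if sliding_plane is not None:
        axis, offset = sliding_plane
        other = _one(rng)
        coord = np.arange(shape[axis]).reshape([-1 if a == axis else 1 for a in range(3)])
        far = np.broadcast_to(coord >= offset, shape)
        u = np.where(far[None], other, u)
    if craniocaudal_bias:
        u = u.copy()
        u[2] += craniocaudal_bias
    return DisplacementField(u)


def radial_field(shape, center, amplitude: float, falloff_radius: float) -> DisplacementField:
    """Radial compression/expansion field about ``center``:
    g_i(x) = amplitude * (x_i - c_i) * exp(-|x-c|^2 / (2 falloff^2)).

    Positive amplitude points outward; used to build phantoms whose moving
    phase carries a localized volume change (a "compressible" object)."""
    c = np.asarray(center, dtype=np.float64)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    rel = np.stack([g - ci for g, ci in zip(grids, c)])
    r2 = np.sum(rel ** 2, axis=0)
    w = np.exp(-r2 / (2.0 * falloff_radius ** 2))
    return DisplacementField(amplitude * rel * w[None])


def invert_field(field: DisplacementField, n_iter: int = 30, tol: float = 1e-4) -> DisplacementField:
    """Fixed-point inversion: psi with psi(y) = -g(y + psi(y)).

    Converges for fields with Jacobian perturbation below 1; the phantoms'
    smooth fields are well within that regime.
    """
    g = field.u.astype(np.float64)
    shape = field.grid_shape
    ident = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                                 indexing="ij")).reshape(3, -1)
    psi = np.zeros_like(ident)
    for _ in range(n_iter):
        coords = ident + psi
        new = -np.stack(trilinear_sample_multi([g[0], g[1], g[2]], coords))
        delta = np.max(np.abs(new - psi))
        psi = new
        if delta < tol:
            break
    return DisplacementField(psi.reshape(3, *shape))


def _object_profiles(spec: PhantomSpec, coords: np.ndarray):
    """Partial-volume object indicators (1 inside, 0 outside, one-voxel
    linear falloff) for liver and lesion at arbitrary continuous coords."""
    c = np.asarray(spec.liver_center, dtype=np.float64)
    ax = np.asarray(spec.liver_axes, dtype=np.float64)
    rel = (coords - c[:, None]) / ax[:, None]
    rho = np.sqrt(np.sum(rel ** 2, axis=0))
    # approximate signed distance to the ellipsoid: (rho - 1) / |grad rho|
    grad = np.sqrt(np.sum((rel / ax[:, None]) ** 2, axis=0))
    grad = np.maximum(grad, 1e-12)
    d_liver = (rho - 1.0) / grad
    lc = np.asarray(spec.lesion_center, dtype=np.float64)
    d_lesion = np.sqrt(np.sum((coords - lc[:, None]) ** 2, axis=0)) - spec.lesion_radius
    t_liver = np.clip(0.5 - d_liver, 0.0, 1.0)
    t_lesion = np.clip(0.5 - d_lesion, 0.0, 1.0)
    return t_liver, t_lesion


def _make_texture(spec: PhantomSpec, seed: int) -> np.ndarray | None:
    """Smooth anatomical texture (vessels, parenchymal heterogeneity) in the
    reference geometry; shared across phases because it is anatomy, not
    noise.  Without it, interior correspondence would be unobservable to any
    windowed-correlation similarity (flat regions carry no information)."""
    if spec.texture_amplitude <= 0:
        return None
    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), spec.texture_sigma)
    sd = raw.std()
    if sd < 1e-12:
        return None
    return raw * (spec.texture_amplitude / sd)


def _render(spec: PhantomSpec, phase: str, coords: np.ndarray,
            texture: np.ndarray | None = None):
    bg, liver, lesion = spec.intensities[phase]
    t_liver, t_lesion = _object_profiles(spec, coords)
    img = bg + t_liver * (liver - bg) + t_lesion * (lesion - liver)
    if texture is not None:
        img = img + trilinear_sample(texture, coords)
    return img, t_liver >= 0.5, t_lesion >= 0.5


def make_phantom(spec: PhantomSpec,
                 fields: dict | None = None) -> tuple[Study, GroundTruth]:
    """Render the three-phase study and its ground truth.

    The AP phase sits on the reference grid; Pre and DP are rendered in
    deformed geometry via analytically composed inverse fields.  Seeded
    Gaussian noise is added per phase; all randomness flows from
    ``spec.seed``.  Should a deformation push the lesion outside the liver
    (possible only through rendering edge effects), the phantom is
    regenerated with 20% smaller magnitude.
    """
    shape = spec.grid_shape
    ident = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                                 indexing="ij")).reshape(3, -1)
    rng = np.random.default_rng(spec.seed)
    field_seeds = {"Pre": int(rng.integers(2 ** 31)), "DP": int(rng.integers(2 ** 31))}
    noise_seeds = {ph: int(rng.integers(2 ** 31)) for ph in ("Pre", "AP", "DP")}
    texture = _make_texture(spec, int(rng.integers(2 ** 31)))

    images: dict[str, PhaseImage] = {}
    livers: dict[str, MaskVolume] = {}
    lesions: dict[str, MaskVolume] = {}
    gt_fields: dict[str, DisplacementField] = {}

    for ph in ("Pre", "AP", "DP"):
        if fields is not None and ph in fields:
            g = fields[ph]
            psi = invert_field(g)
            coords = ident + psi.u.reshape(3, -1)
            gt_fields[ph] = g
        elif ph == "AP" or spec.max_magnitude == 0:
            coords = ident
            if ph != "AP":
                gt_fields[ph] = DisplacementField.zeros(shape)
        else:
            g = random_smooth_field(shape, spec.max_magnitude / min(spec.spacing),
                                    spec.smoothness_sigma,
                                    sliding_plane=spec.sliding_plane,
                                    seed=field_seeds[ph],
                                    craniocaudal_bias=spec.craniocaudal_bias)
            psi = invert_field(g)
            coords = ident + psi.u.reshape(3, -1)
            gt_fields[ph] = g
        img, liver, lesion = _render(spec, ph, coords, texture)
        if (lesion & ~liver).any():
            log.warning("lesion escaped liver in phase %s; regenerating with "
                        "reduced deformation", ph)
            smaller = replace(spec, max_magnitude=0.8 * spec.max_magnitude)
            return make_phantom(smaller)
        img = img.reshape(shape)
        if spec.noise_sigma > 0:
            nrng = np.random.default_rng(noise_seeds[ph])
            img = img + nrng.normal(0.0, spec.noise_sigma, size=shape)
        img = np.clip(img, 0.0, 1.0)
        images[ph] = PhaseImage(img, spacing=spec.spacing, phase=ph, normalized=True)
        livers[ph] = MaskVolume(liver.reshape(shape).astype(np.uint8),
                                spacing=spec.spacing, role="liver")
        lesions[ph] = MaskVolume(lesion.reshape(shape).astype(np.uint8),
                                 spacing=spec.spacing, role="lesion")

    study = Study(pre=images["Pre"], ap=images["AP"], dp=images["DP"],
                  liver_masks=livers, lesion_masks=lesions)
    gt = GroundTruth(fields=gt_fields,
                     masks={"liver": livers, "lesion": lesions},
                     expected_features=spec.expected_features())
    return study, gt
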