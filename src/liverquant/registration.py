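"""Piecewise-smooth nonlinear registration by iteratively reweighted LCC.

The engine minimizes, over a displacement field u on the fixed grid,

    E(u) = - sum_x LCC(x; u)
           + alpha * sum_x Phi( sum_i |grad u_i(x)|^2 )
           + beta  * sum_x grad(l_R) . u(x)

where LCC is the squared local cross-correlation of the fixed image and the
warped moving image over cubic windows, Phi is a robust (TV-like) penalty
making the field piecewise smooth so sliding motion at the liver boundary is
tolerated, and l_R is a smoothed ROI indicator whose linear term biases the
solution toward volume preservation inside the ROI.

Optimization is coarse-to-fine over a Gaussian pyramid.  At each level the
energy is linearized in an increment h around the current field
(I2(x+u+h) ~ I2(x+u) + grad I2(x+u) . h), yielding one 3x3 system per voxel
coupled by a lagged-diffusivity weighted Laplacian; the system is relaxed
with red-black successive over-relaxation (SOR).

Discretization conventions (these define the energy the solver descends):

* window statistics use clipped windows with exact clipped-size
  normalization;
* the regularizer uses forward differences with Neumann (zero-flux)
  boundaries; its lagged-diffusivity weight is W = 2 Phi'(s);
* the right-hand side of the assembled system is the exact negative
  gradient of the discrete energy, aggregating the per-window LCC weights
  over every window containing a voxel;
* warping uses clamped trilinear interpolation, and image gradients in the
  data term are the analytic derivatives of that interpolant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (DisplacementField, MaskVolume, PhaseImage, box_sum,
                   image_gradient, sample_with_gradient, warp_image, warp_mask,
                   window_counts)

log = logging.getLogger(__name__)

_EPS_AB = 1e-8  # degenerate (flat) window guard on A and B


def _window_volume(params: "RegistrationParams") -> float:
    """Normalization of the LCC sum by the window volume.

    The per-voxel linearized system divides the correlation forces by the
    window volume; the stage weights alpha/beta are calibrated against that
    per-window-mean convention, so the discrete energy adopts it too (the
    assembled system stays the exact gradient of this energy).
    """
    return float((2 * params.window_radius + 1) ** 3)


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationParams:
    """Hyperparameters of one nonlinear registration stage.

    Defaults are the coarse (liver-ROI) stage; :meth:`fine` gives the
    lesion-ROI refinement stage.
    """

    alpha: float = 0.001          # regularization weight
    beta: float = 0.001           # volume-prior weight
    out_iter: int = 5             # outer (re-linearization) iterations
    in_iter: int = 1              # inner solves per outer iteration
    sor_sweeps: int = 20          # SOR sweeps per inner solve
    sor_omega: float = 1.8        # SOR relaxation factor
    coarsest_size: int = 32       # longest axis of the coarsest pyramid level
    eta: float = 0.75             # pyramid downsampling rate
    window_radius: int = 3        # LCC window radius (7x7x7)
    epsilon: float = 0.001        # Phi smoothing constant
    pyramid_sigma: float = 0.6    # Gaussian prefilter per pyramid step
    roi_sigma: float = 1.0        # smoothing of the ROI indicator
    phi_as_printed: bool = False  # alternative Phi composition (see methods)
    step_max: float = 1.0         # trust region: per-voxel increment clamp (voxels)
    backtrack: int = 6            # energy backtracking halvings per outer iteration

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise ValueError("eta must be in (0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if not 0 < self.sor_omega < 2:
            raise ValueError("sor_omega must be in (0, 2)")

    @classmethod
    def coarse(cls, **kw) -> "RegistrationParams":
        return cls(**kw)

    @classmethod
    def fine(cls, **kw) -> "RegistrationParams":
        base = dict(alpha=0.00015, beta=0.0001, out_iter=3)
        base.update(kw)
        return cls(**base)


@dataclass
class LocalStats:
    """Windowed first/second moments of the fixed and warped-moving images.

    ``A = |w_x| v1`` and ``B = |w_x| v2`` are the windowed sums of squared
    deviations, ``c`` the windowed sum of cross deviations (so the squared
    cross term is C = c^2), and ``gt`` the pointwise LCC residual.
    """

    mu1: np.ndarray
    mu2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    v12: np.ndarray
    A: np.ndarray
    B: np.ndarray
    c: np.ndarray
    gt: np.ndarray
    counts: np.ndarray
    i1: np.ndarray
    i2w: np.ndarray
    radius: int

    @property
    def C(self) -> np.ndarray:
        return self.c ** 2


def local_stats(fixed: PhaseImage | np.ndarray, warped_moving: PhaseImage | np.ndarray,
                window_radius: int = 3) -> LocalStats:
    i1 = np.asarray(fixed.data if isinstance(fixed, PhaseImage) else fixed, dtype=np.float64)
    i2 = np.asarray(warped_moving.data if isinstance(warped_moving, PhaseImage)
                    else warped_moving, dtype=np.float64)
    if i1.shape != i2.shape:
        raise ValueError("local_stats expects both volumes on one grid")
    r = int(window_radius)
    n = window_counts(i1.shape, r)
    s1 = box_sum(i1, r)
    s2 = box_sum(i2, r)
    s11 = box_sum(i1 * i1, r)
    s22 = box_sum(i2 * i2, r)
    s12 = box_sum(i1 * i2, r)
    mu1 = s1 / n
    mu2 = s2 / n
    a = s11 - s1 * mu1
    b = s22 - s2 * mu2
    c = s12 - s1 * mu2
    np.maximum(a, 0.0, out=a)
    np.maximum(b, 0.0, out=b)
    with np.errstate(divide="ignore", invalid="ignore"):
        gt = (i1 - mu1) - np.where(b > _EPS_AB, c / np.where(b > _EPS_AB, b, 1.0), 0.0) * (i2 - mu2)
    return LocalStats(mu1=mu1, mu2=mu2, v1=a / n, v2=b / n, v12=c / n,
                      A=a, B=b, c=c, gt=gt, counts=n, i1=i1, i2w=i2, radius=r)


def local_correlation(stats: LocalStats) -> np.ndarray:
    """Pointwise local correlation v12 / sqrt(v1 v2); 0 on flat windows."""
    denom = stats.v1 * stats.v2
    valid = denom > 0
    out = np.zeros_like(stats.v12)
    out[valid] = stats.v12[valid] / np.sqrt(denom[valid])
    return out


# ---------------------------------------------------------------------------
# Robust regularizer
# ---------------------------------------------------------------------------

def _grad_energy(u: np.ndarray) -> np.ndarray:
    """s(x) = sum_i |grad^+ u_i(x)|^2 with forward differences, Neumann."""
    s = np.zeros(u.shape[1:], dtype=u.dtype)
    for i in range(3):
        for ax in range(3):
            d = np.diff(u[i], axis=ax)
            sl = [slice(None)] * 3
            sl[ax] = slice(0, -1)
            s[tuple(sl)] += d * d
    return s


def _phi(s: np.ndarray, eps: float, as_printed: bool) -> np.ndarray:
    if as_printed:
        return np.sqrt(s * s + eps * eps)
    return np.sqrt(s + eps * eps)


def _phi_weight(s: np.ndarray, eps: float, as_printed: bool) -> np.ndarray:
    """Lagged-diffusivity weight W = 2 Phi'(s)."""
    if as_printed:
        return 2.0 * s / np.sqrt(s * s + eps * eps)
    return 1.0 / np.sqrt(s + eps * eps)


def _weighted_laplacian(w: np.ndarray, v: np.ndarray) -> np.ndarray:
    """(L_w v)(x) = -div(w grad v) with forward differences and Neumann
    boundaries; positive semidefinite for w >= 0."""
    out = np.zeros_like(v)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        flux = w[lo] * (v[hi] - v[lo])
        out[lo] -= flux
        out[hi] += flux
    return out


def smoothed_roi_gradient(roi, sigma: float = 1.0) -> np.ndarray:
    """Gradient of the Gaussian-smoothed ROI indicator (shape (3,) + grid)."""
    if roi is None:
        return None
    dat = roi.data if isinstance(roi, MaskVolume) else np.asarray(roi)
    ell = ndimage.gaussian_filter(dat.astype(np.float64), sigma)
    return image_gradient(ell)


# ---------------------------------------------------------------------------
# Energy (testing / monitoring only; the solver never calls this)
# ---------------------------------------------------------------------------

def energy(fixed, moving, u: DisplacementField, params: RegistrationParams,
           roi_mask=None, prior_grad: np.ndarray | None = None,
           data_mask: np.ndarray | None = None,
           return_parts: bool = False):
    """Discrete registration energy at displacement ``u``.

    ``data_mask`` (optional) restricts the correlation sum to windows
    centered inside the mask.
    """
    i1 = np.asarray(fixed.data if isinstance(fixed, PhaseImage) else fixed, dtype=np.float64)
    i2 = np.asarray(moving.data if isinstance(moving, PhaseImage) else moving, dtype=np.float64)
    uu = u.u.astype(np.float64)
    coords = _identity_coords(i1.shape) + uu.reshape(3, -1)
    j = np.asarray(trilinear_flat(i2, coords)).reshape(i1.shape)
    st = local_stats(i1, j, params.window_radius)
    if prior_grad is None and roi_mask is not None:
        prior_grad = smoothed_roi_gradient(roi_mask, params.roi_sigma)
    return _energy_from_stats(st, uu, params, prior_grad, data_mask,
                              return_parts=return_parts)


def _energy_from_stats(st: LocalStats, uu: np.ndarray, params: RegistrationParams,
                       prior_grad, data_mask, return_parts: bool = False):
    valid = (st.A > _EPS_AB) & (st.B > _EPS_AB)
    if data_mask is not None:
        valid &= np.asarray(data_mask, dtype=bool)
    lcc = np.zeros_like(st.A)
    lcc[valid] = st.c[valid] ** 2 / (st.A[valid] * st.B[valid])
    e_data = -float(np.sum(lcc)) / _window_volume(params)
    s = _grad_energy(uu)
    e_reg = params.alpha * float(np.sum(_phi(s, params.epsilon, params.phi_as_printed)))
    e_prior = 0.0
    if prior_grad is not None and params.beta > 0:
        e_prior = params.beta * float(np.sum(prior_grad * uu))
    total = e_data + e_reg + e_prior
    if return_parts:
        return total, {"data": e_data, "reg": e_reg, "prior": e_prior}
    return total


def trilinear_flat(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    from .core import trilinear_sample
    return trilinear_sample(vol, coords)


def _identity_coords(shape) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    return np.stack(grids).reshape(3, -1)


# ---------------------------------------------------------------------------
# System assembly and SOR
# ---------------------------------------------------------------------------

@dataclass
class LinearSystem:
    """Per-voxel 3x3 blocks ``s3 * g g^T + alpha * sigma_w I`` coupled by the
    weighted Laplacian; ``b`` is the exact negative energy gradient at u."""

    s3: np.ndarray      # data weight, grid shape
    g: np.ndarray       # warped-image gradient, (3,) + grid
    w: np.ndarray       # lagged-diffusivity weight, grid shape
    alpha: float
    b: np.ndarray       # right-hand side, (3,) + grid

    def apply(self, h: np.ndarray) -> np.ndarray:
        """Matrix-vector product M h of the linearized stationarity system."""
        gh = np.einsum("i...,i...->...", self.g, h)
        out = self.s3 * gh * self.g
        for i in range(3):
            out[i] += self.alpha * _weighted_laplacian(self.w, h[i])
        return out

    def residual(self, h: np.ndarray) -> np.ndarray:
        return self.b - self.apply(h)

    def astype(self, dtype) -> "LinearSystem":
        return LinearSystem(s3=self.s3.astype(dtype), g=self.g.astype(dtype),
                            w=self.w.astype(dtype), alpha=float(self.alpha),
                            b=self.b.astype(dtype))


def assemble_system(stats: LocalStats, grad_warped: np.ndarray, u: DisplacementField,
                    params: RegistrationParams, roi_mask=None,
                    prior_grad: np.ndarray | None = None,
                    data_mask: np.ndarray | None = None) -> LinearSystem:
    """Linearize the energy around ``u``: returns the system M h = b whose
    solution is the displacement increment.

    The data block aggregates the LCC window weights over every window
    containing a voxel (box sums), so that ``b`` is the exact negative
    gradient of the discrete energy; the flat-window guard zeroes the data
    term where A or B fall below 1e-8.
    """
    a, bb, c = stats.A, stats.B, stats.c
    valid = (a > _EPS_AB) & (bb > _EPS_AB)
    if data_mask is not None:
        valid &= np.asarray(data_mask, dtype=bool)
    safe_a = np.where(valid, a, 1.0)
    safe_b = np.where(valid, bb, 1.0)
    inv_n = 1.0 / _window_volume(params)
    f1 = np.where(valid, 2.0 * inv_n * c / (safe_a * safe_b), 0.0)
    f2 = np.where(valid, f1 * c / safe_b, 0.0)
    r = stats.radius
    bs_f1 = box_sum(f1, r)
    bs_f1m = box_sum(f1 * stats.mu1, r)
    bs_f2 = box_sum(f2, r)
    bs_f2m = box_sum(f2 * stats.mu2, r)
    # dE_data / dJ(y), J the warped moving image
    dedj = -stats.i1 * bs_f1 + bs_f1m + stats.i2w * bs_f2 - bs_f2m

    uu = u.u.astype(np.float64)
    s = _grad_energy(uu)
    w = _phi_weight(s, params.epsilon, params.phi_as_printed)

    b = np.empty_like(uu)
    for i in range(3):
        b[i] = -dedj * grad_warped[i] - params.alpha * _weighted_laplacian(w, uu[i])
    if prior_grad is None and roi_mask is not None:
        prior_grad = smoothed_roi_gradient(roi_mask, params.roi_sigma)
    if prior_grad is not None and params.beta > 0:
        b -= params.beta * prior_grad

    s3 = np.maximum(bs_f2, 0.0)
    return LinearSystem(s3=s3, g=np.asarray(grad_warped, dtype=np.float64),
                        w=w, alpha=params.alpha, b=b)


def _face_weight_sum(w: np.ndarray) -> np.ndarray:
    """Diagonal of the weighted Laplacian: sum of incident face weights."""
    sigma = np.zeros_like(w)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        sigma[tuple(lo)] += w[tuple(lo)]
        sigma[tuple(hi)] += w[tuple(lo)]
    return sigma


def _neighbor_sum(w: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Off-diagonal part: nb_i(x) = sum over faces of w_face * h_i(neighbor)."""
    out = np.zeros_like(h)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        lo = (slice(None), *lo)
        hi = (slice(None), *hi)
        wf = w[lo[1:]]
        out[lo] += wf * h[hi]
        out[hi] += wf * h[lo]
    return out


def _parity_mask(shape) -> np.ndarray:
    ix, iy, iz = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    return ((ix + iy + iz) % 2).astype(bool)


def sor_solve(system: LinearSystem, h0: DisplacementField | np.ndarray | None,
              sweeps: int = 20, omega: float = 1.8,
              update_mask: np.ndarray | None = None) -> np.ndarray:
    """Red-black block-SOR on the coupled 3-component system.

    Each voxel's 3x3 block (rank-one data part plus a positive diagonal) is
    inverted in closed form via the Sherman-Morrison identity.  With
    ``update_mask`` the increment is solved only inside the mask (Dirichlet
    zero outside), leaving the field elsewhere untouched.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if not 0 < omega < 2:
        raise ValueError("omega must be in (0, 2)")
    if h0 is None:
        h = np.zeros_like(system.b)
    elif isinstance(h0, DisplacementField):
        h = h0.u.astype(system.b.dtype).copy()
    else:
        h = np.asarray(h0, dtype=system.b.dtype).copy()
    shape = system.w.shape
    black = _parity_mask(shape)
    if update_mask is not None:
        um = np.asarray(update_mask, dtype=bool)
        colors = (~black & um, black & um)
    else:
        colors = (~black, black)
    sigma = system.alpha * _face_weight_sum(system.w) + np.asarray(1e-30, dtype=system.w.dtype)
    g = system.g
    g2 = np.einsum("i...,i...->...", g, g)
    denom = sigma + system.s3 * g2
    for _ in range(int(sweeps)):
        for color in colors:
            nb = _neighbor_sum(system.w, h)
            r = system.b + system.alpha * nb
            gr = np.einsum("i...,i...->...", g, r)
            coef = system.s3 * gr / denom
            h_new = (r - coef * g) / sigma
            for i in range(3):
                h[i][color] = (1.0 - omega) * h[i][color] + omega * h_new[i][color]
    return h


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------

@dataclass
class Pyramid:
    """Coarse-to-fine image pyramid: ``levels[0]`` is the coarsest."""

    levels: list = field(default_factory=list)   # list of np.ndarray
    scales: list = field(default_factory=list)   # per-level scale factor
    n_levels: int = 1


def num_levels(shape, eta: float, coarsest_size: int) -> int:
    longest = max(shape)
    if longest <= coarsest_size:
        return 1
    return 1 + math.ceil(math.log(coarsest_size / longest) / math.log(eta))


def _level_shapes(shape, eta: float, n: int) -> list:
    return [tuple(max(2, int(round(d * eta ** (n - 1 - l)))) for d in shape)
            for l in range(n)]


def _resize(vol: np.ndarray, new_shape, order: int = 1) -> np.ndarray:
    """Align-corners resampling onto a target shape."""
    if tuple(vol.shape) == tuple(new_shape):
        return np.array(vol, copy=True)
    axes = [np.linspace(0.0, n - 1.0, ns) if ns > 1 else np.array([(n - 1.0) / 2.0])
            for n, ns in zip(vol.shape, new_shape)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.astype(np.float64), np.stack(coords).reshape(3, -1),
                                  order=order, mode="nearest")
    return out.reshape(new_shape)


def build_pyramid(img: PhaseImage | np.ndarray, params: RegistrationParams) -> Pyramid:
    """Dense Gaussian pyramid: each step Gaussian-prefilters then resamples
    by the rate eta; the finest level is the original image."""
    vol = np.asarray(img.data if isinstance(img, PhaseImage) else img, dtype=np.float64)
    n = num_levels(vol.shape, params.eta, params.coarsest_size)
    shapes = _level_shapes(vol.shape, params.eta, n)
    levels = [None] * n
    levels[-1] = vol
    for l in range(n - 2, -1, -1):
        sm = ndimage.gaussian_filter(levels[l + 1], params.pyramid_sigma)
        levels[l] = _resize(sm, shapes[l], order=1)
    scales = [params.eta ** (n - 1 - l) for l in range(n)]
    return Pyramid(levels=levels, scales=scales, n_levels=n)


def _upsample_field(u: np.ndarray, new_shape) -> np.ndarray:
    """Trilinear component upsampling with per-axis magnitude rescaling."""
    out = np.empty((3, *new_shape), dtype=u.dtype)
    for i in range(3):
        ratio = (new_shape[i] - 1) / max(u.shape[1 + i] - 1, 1)
        out[i] = _resize(u[i], new_shape, order=1) * ratio
    return out


# ---------------------------------------------------------------------------
# Pairwise and study-level registration
# ---------------------------------------------------------------------------

def register_pair(fixed: PhaseImage, moving: PhaseImage, params: RegistrationParams,
                  roi_mask: MaskVolume | None = None,
                  u_init: DisplacementField | None = None,
                  data_mask: MaskVolume | None = None,
                  record: list | None = None) -> DisplacementField:
    """Coarse-to-fine fixed-point IRLCC registration of one image pair.

    Returns the displacement field on the fixed grid (voxel units, backward
    convention).  ``u_init`` (e.g. a previous stage's field) initializes the
    coarsest level after resampling.
    """
    if fixed.shape != moving.shape:
        raise ValueError("register_pair expects preprocessed images on one grid")
    pyr_f = build_pyramid(fixed, params)
    pyr_m = build_pyramid(moving, params)
    n = pyr_f.n_levels
    shapes = [lv.shape for lv in pyr_f.levels]

    roi_soft = None
    if roi_mask is not None and params.beta > 0:
        roi_soft = roi_mask.data.astype(np.float64)
    dmask_soft = None
    if data_mask is not None:
        dmask_soft = data_mask.data.astype(np.float64)

    # With an initial field the pyramid variable is the correction delta;
    # the base field is resampled to each level directly from full
    # resolution, so an untouched region keeps the initial field exactly.
    base_full = u_init.u.astype(np.float64) if u_init is not None else None

    def _base(shape):
        if base_full is None:
            return 0.0
        return _upsample_field(base_full, shape)

    delta = np.zeros((3, *shapes[0]), dtype=np.float64)
    u = _base(shapes[0]) + delta

    for l in range(n):
        f_l, m_l = pyr_f.levels[l], pyr_m.levels[l]
        if l > 0:
            delta = _upsample_field(delta, shapes[l])
            u = _base(shapes[l]) + delta
        prior_grad = None
        if roi_soft is not None:
            ell = ndimage.gaussian_filter(_resize(roi_soft, shapes[l], order=1),
                                          params.roi_sigma)
            prior_grad = image_gradient(ell)
        dmask_l = None
        if dmask_soft is not None:
            dmask_l = _resize(dmask_soft, shapes[l], order=1) > 0.5
        ident = _identity_coords(shapes[l])
        for it in range(params.out_iter):
            coords = ident + u.reshape(3, -1)
            j_flat, g_flat = sample_with_gradient(m_l, coords)
            j = j_flat.reshape(shapes[l])
            g = g_flat.reshape((3, *shapes[l]))
            stats = local_stats(f_l, j, params.window_radius)
            e_cur = _energy_from_stats(stats, u, params, prior_grad, dmask_l)
            system = assemble_system(stats, g, DisplacementField(u), params,
                                     prior_grad=prior_grad, data_mask=dmask_l)
            # single precision is ample for sub-voxel increments and about
            # halves the SOR cost
            system32 = system.astype(np.float32)
            h = np.zeros_like(system32.b)
            for _ in range(params.in_iter):
                h = sor_solve(system32, h, sweeps=params.sor_sweeps,
                              omega=params.sor_omega, update_mask=dmask_l)
            h = h.astype(np.float64)
            if not np.all(np.isfinite(h)):
                raise RegistrationError(
                    f"non-finite increment at level {l + 1}/{n}, outer iteration {it + 1}")
            # trust region: the linearization I2(x+u+h) is only valid for
            # sub-voxel increments, so clamp the per-voxel magnitude
            if params.step_max > 0:
                mag = np.sqrt(np.sum(h * h, axis=0))
                scale = np.minimum(1.0, params.step_max / np.maximum(mag, 1e-30))
                h = h * scale
            # energy backtracking keeps the fixed-point update a descent step
            accepted = False
            for _ in range(max(params.backtrack, 1)):
                e_new = energy(f_l, m_l, DisplacementField(u + h), params,
                               prior_grad=prior_grad, data_mask=dmask_l)
                if e_new <= e_cur:
                    accepted = True
                    break
                h = 0.5 * h
            if accepted:
                u = u + h
                delta = delta + h
                e_cur = e_new
            if record is not None:
                record.append({"level": l + 1, "outer": it + 1, "energy": e_cur,
                               "mean_h": float(np.mean(np.abs(h))),
                               "accepted": accepted})
            if not accepted:
                break
        log.info("register_pair: level %d/%d done (shape %s)", l + 1, n, shapes[l])
    return DisplacementField(u)


@dataclass
class StudyRegistration:
    """Two-stage registration output for both moving phases (fixed = AP)."""

    warped_pre: PhaseImage
    warped_dp: PhaseImage
    field_pre: DisplacementField
    field_dp: DisplacementField
    coarse_fields: dict = field(default_factory=dict)
    warped_liver_masks: dict = field(default_factory=dict)
    warped_lesion_masks: dict = field(default_factory=dict)


def register_study(study, coarse: RegistrationParams | None = None,
                   fine: RegistrationParams | None = None,
                   fine_data_masked: bool = True) -> StudyRegistration:
    """Register Pre and DP to AP: stage 1 with the liver ROI, stage 2
    (initialized from stage 1) with the lesion ROI; warps the moving-phase
    masks with nearest-neighbor sampling for evaluation.

    The fine stage serves lesion-area matching; with ``fine_data_masked``
    its correlation term is restricted to a dilated lesion neighborhood so
    the rest of the field keeps the liver-stage solution.
    """
    coarse = coarse or RegistrationParams.coarse()
    fine = fine or RegistrationParams.fine()
    for ph in ("Pre", "DP"):
        if ph not in study.liver_masks or ph not in study.lesion_masks:
            raise ValueError(f"missing liver/lesion mask for phase {ph}")
    out: dict[str, dict] = {}
    for ph, moving in (("Pre", study.pre), ("DP", study.dp)):
        u1 = register_pair(study.ap, moving, coarse, roi_mask=study.liver_masks[ph])
        dmask = None
        if fine_data_masked:
            # only windows fully interior to the lesion: windows straddling
            # the boundary mix lesion-present and lesion-absent phase
            # content and destabilize the refinement
            core = ndimage.binary_erosion(study.lesion_masks[ph].astype_bool(),
                                          iterations=fine.window_radius)
            if not core.any():
                core = study.lesion_masks[ph].astype_bool()
            dmask = MaskVolume(core.astype(np.uint8),
                               spacing=study.lesion_masks[ph].spacing, role="lesion")
        u2 = register_pair(study.ap, moving, fine, roi_mask=study.lesion_masks[ph],
                           u_init=u1, data_mask=dmask)
        out[ph] = {
            "field": u2,
            "coarse_field": u1,
            "warped": warp_image(moving, u2),
            "liver": warp_mask(study.liver_masks[ph], u2),
            "lesion": warp_mask(study.lesion_masks[ph], u2),
        }
    return StudyRegistration(
        warped_pre=out["Pre"]["warped"], warped_dp=out["DP"]["warped"],
        field_pre=out["Pre"]["field"], field_dp=out["DP"]["field"],
        coarse_fields={ph: out[ph]["coarse_field"] for ph in out},
        warped_liver_masks={ph: out[ph]["liver"] for ph in out},
        warped_lesion_masks={ph: out[ph]["lesion"] for ph in out},
    )
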