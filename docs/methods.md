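# Methods

## Problem setting

Multiphase liver CT acquires the same anatomy at different times after
contrast injection. Breath-hold differences between acquisitions deform
the liver (large cranio-caudal displacement, distortion near diaphragm and
ribs, and sliding of the liver against the abdominal wall), so a voxel-wise
comparison of phases requires nonlinear registration first. The package
registers the pre-contrast (Pre) and delayed (DP) phases to the arterial
phase (AP), then applies a subtraction calculus to flag and grade
arterial-phase hyperenhancement (APHE) and washout (WO) voxel by voxel.

## Registration model

The displacement field u (voxel units, backward/pull-back convention:
`warped(x) = moving(x + u(x))`) minimizes

    E(u) = − (1/|ω|) Σ_x LCC(x; u)
           + α Σ_x Φ( Σ_i |∇⁺u_i(x)|² )
           + β Σ_x ∇ℓ_R(x) · u(x)

* **Data term.** LCC(x) = c(x)² / (A(x)·B(x)) with A, B the windowed sums
  of squared deviations of the fixed and warped-moving image and c the
  windowed sum of cross deviations, over cubic windows of radius 3
  (7×7×7). LCC is invariant to local linear intensity maps, which is what
  makes cross-phase matching possible: contrast changes the local linear
  relation between phases but not its existence. Windows are clipped at
  the volume boundary with exact clipped-size normalization, so constants
  are exactly invariant. Windows whose A or B falls below 1e-8 are treated
  as non-informative and contribute nothing.

  The `1/|ω|` normalization (|ω| = 343) is a deliberate calibration
  convention: the per-voxel linearized solver applies the correlation
  force of one window per voxel, and the stage weights α, β are calibrated
  against that per-window-mean scale. Without the normalization the exact
  gradient of the correlation sum (which aggregates every window containing
  a voxel) outweighs the regularizer by roughly the window volume, and the
  model degenerates into per-voxel intensity chasing.

* **Regularizer.** Φ(s) = √(s + ε²) with ε = 1e-3 applied to the summed
  squared forward differences of the three components — a smoothed total
  variation of the field. Its lagged-diffusivity weight W = 2Φ′(s) =
  1/√(s + ε²) yields strong diffusion where the field is smooth and almost
  none across motion discontinuities, which is the model's answer to
  sliding motion (no explicit interface segmentation). An alternative
  composition Φ(s) = √(s² + ε²) — asymptotically quadratic rather than
  TV-like — is available behind `phi_as_printed=True` for comparison.

* **Volume prior.** ℓ_R is the ROI indicator of the moving image (liver
  mask in the first stage, lesion mask in the second), Gaussian-smoothed
  with σ = 1 voxel so its gradient is a volume field on a shell around the
  boundary rather than a surface measure. The linear term β ∇ℓ_R·u equals
  −β ∫_R div u after summation by parts: it biases the transform toward
  non-negative divergence inside the ROI, i.e. against volume inflation of
  the warped object. It is one-sided; the ablation experiment constructs
  the compressible phantom in the direction the prior counteracts.

### Discretization and solver

Each outer iteration linearizes the warped moving image,
I₂(x+u+h) ≈ I₂(x+u) + ∇I₂(x+u)·h, with ∇I₂ the *analytic* derivative of
the clamped trilinear interpolant (not a resampled difference image), so
the assembled per-voxel 3×3 system

    ( S₃(x) ∇I₂ ∇I₂ᵀ + α L_W ) h = b,    b = −∇E(u)

is the exact stationarity condition of the discrete energy linearized in
h. The right-hand side is verified against central finite differences of
the energy (relative tolerance 1e-4); this oracle, not any printed
coefficient, defines the correct C/(A·Bᵖ) scalings. S₃ is the box-summed
Gauss-Newton weight Σ_windows 2c²/(AB²) ≥ 0; L_W the weighted Laplacian
with forward differences and Neumann (zero-flux) boundaries, W frozen at
the current iterate. The system is symmetric positive (semi)definite.

The solve uses red-black block-SOR: per voxel the 3×3 block is a rank-one
data part plus a positive diagonal, inverted in closed form with the
Sherman–Morrison identity; ω = 1.8 by default (sweep count 20 is a stage
parameter). Within `register_pair` the sweeps run in single precision
(sub-voxel increments need no more), everything else in double.

Two safeguards stabilize the fixed-point update, which the bare iteration
lacks: the per-voxel increment is clamped to `step_max` = 1 voxel (the
validity radius of the trilinear linearization), and each outer iteration
is accepted only if the energy does not increase, halving the step up to
six times otherwise. Without them the update diverges on piecewise-smooth
inputs.

### Pyramid and stages

A dense Gaussian pyramid with rate η = 0.75 and coarsest longest-axis 32
(Gaussian prefilter σ = 0.6 per step; align-corners trilinear resampling);
level count is derived from the image size. Fields are upsampled between
levels with trilinear component interpolation scaled by the per-axis grid
ratio.

Stage 1 (liver ROI: α = 0.001, β = 0.001, 5 outer × 1 inner × 20 sweeps)
registers the whole cropped volume. Stage 2 (lesion ROI: α = 1.5e-4,
β = 1e-4, 3 outer) re-runs all pyramid levels initialized from the stage-1
field, kept as a full-resolution base plus per-level correction so that
untouched regions retain the stage-1 field exactly. Its correlation term
and update region are restricted to windows fully interior to the lesion:
windows straddling the lesion boundary mix lesion-present (AP) with
lesion-absent (Pre) content whose objectives conflict, and the weaker α of
the refinement stage cannot resist them; interior windows match anatomy
(texture) consistently. The restriction is configurable
(`register_study(fine_data_masked=False)` reproduces the unrestricted
variant).

## Preprocessing

Isotropic resampling to 1×1×1 mm (trilinear for images, nearest-neighbor
for masks), cropping to the union liver bounding box over phases plus a
10-voxel margin, window normalization to [0, 1] (defaults 60/400, a
typical abdominal window; phantoms use 0.5/1.0 which is the identity), and
rigid pre-alignment of each moving phase to AP by Powell maximization of
the global normalized correlation coefficient at half resolution (the NCC
optimum transfers to full resolution well below the voxel scale). The
rigid step never returns a transform whose NCC is below the identity's.

## Quantification conventions

* Adjacent-liver value LM = μ ± 2σ over liver-minus-lesion voxels of the
  aligned volumes; σ is the population standard deviation. The washout
  comparisons use the "darker than liver" polarity
  (mask4 = [Mdp − LMdp < 0], mask5 = [sub2 − LMsub2 < 0]), which makes the
  lesion-to-liver contrast ratio non-negative wherever defined;
  `as_printed=True` flips the comparison for auditability.
* Feature masks are extracted and reported inside the expert lesion mask
  (the volume ratio R sums over the lesion domain); `domain="liver"`
  widens them for exploration.
* PAE divides by the aligned pre-contrast intensity; voxels with
  |Mpre| < 1e-6 receive a NaN sentinel and are excluded from summaries
  rather than silently zeroed.
* LLCR uses the mask4 branch when both mask4 and mask5 hold.

## Synthetic phantoms

The generator renders an ellipsoidal liver (default semi-axes 34/30/27 mm)
with a spherical lesion (default radius 18 mm — the modal 3–5 cm clinical
size class) on a 96³ 1 mm grid, with one-voxel partial-volume falloff at
object boundaries. Default per-phase mean intensities (background, liver,
lesion): Pre 0.05/0.40/0.40, AP 0.05/0.50/0.65, DP 0.05/0.55/0.45 — the
HCC pattern: lesion isodense before contrast, hyperdense in AP, hypodense
in DP. Seeded Gaussian parenchymal texture (sd 0.03, correlation length
2 voxels) is rendered in the reference geometry and shared across phases,
because it is anatomy: without it, flat tissue carries no correspondence
information and any windowed-correlation similarity becomes degenerate
(interior matches are unobservable, and near-zero-variance windows reward
spurious warps through the affine invariance). Independent per-phase
Gaussian noise (σ = 0.01) is added afterwards.

Moving phases are rendered analytically at inverse-displaced coordinates:
a seeded smooth random field g (white noise smoothed with σ = 12 voxels,
rescaled to the requested peak magnitude, optionally with a sliding-plane
discontinuity or cranio-caudal bias) is stored as ground truth in the same
backward convention the registrar estimates, and its inverse (fixed-point
iteration) deforms the rendering, so no resampling artifacts enter the
ground truth. All randomness flows from the single phantom seed.

What the phantom does *not* emulate: realistic CT texture spectra,
vasculature, beam hardening or metal artifacts, genuine sliding interfaces
with organs, inter-phase segmentation inconsistency of expert masks, and
lesion heterogeneity (mosaic enhancement). Passing the benchmarks shows
the pipeline recovers smooth respiratory-scale deformation and clean
contrast patterns; it does not certify performance on clinical data.

## Evaluation and known limits

DSC, symmetric mean surface distance and symmetric Hausdorff distance are
computed on 6-connectivity border voxels of the fixed and warped masks
(moving masks warped with nearest-neighbor sampling), distances in mm via
exact Euclidean distance transforms.

Nearest-neighbor warping of voxelized masks caps the reachable Dice at
roughly 1 − 3·q/r for an object of radius r voxels, with q ≈ 0.12 voxel of
double-quantization boundary error — about 0.988 for the liver and 0.980
for an 18 mm lesion *even for the exact ground-truth field*. Liver-scale
benchmarks sit below this cap comfortably; the lesion Dice benchmark is
quantization-limited, not registration-limited, and a lesion large enough
to escape the cap would not fit inside the liver. The pre-contrast lesion
is additionally isodense by construction, so its boundary is anchored only
by texture.

Benchmark problem sizes: 5 phantoms per deformation level (6 mm and
10 mm peak) on 96³ grids; the volume-prior ablation uses a 64³ phantom
with a radial lesion contraction of relative amplitude 0.25. A full
two-stage study registration takes about one minute per phantom on one
CPU core.

Other limitations: no diffeomorphism or inverse-consistency guarantee; the
volume prior is a one-sided linear bias, not a divergence penalty; the
rigid stage searches rotations up to ±0.35 rad only; mask logic assumes
the expert lesion mask is given (no detection).
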