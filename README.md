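# liverquant

Registration-based 3D voxel-wise quantification of the two major imaging
features of hepatocellular carcinoma (HCC) in multiphase contrast-enhanced
liver CT: **arterial-phase hyperenhancement (APHE)** and **washout (WO)**.

These are the features whose definitions drive standardized liver imaging
reporting (LI-RADS v2018). Radiologists assess them visually on 2D slices,
which is subjective and ignores most of the lesion volume. `liverquant` makes the
assessment quantitative and volumetric: it aligns the pre-contrast (Pre)
and delayed-phase (DP) volumes to the arterial phase (AP) with a
piecewise-smooth nonlinear registration, then extracts feature locations
and per-voxel values by dynamic subtraction against the surrounding liver.

## The model

**Registration.** Pre→AP and DP→AP displacement fields u minimize

    E(u) = − Σ_x LCC(x; u) / |ω|
           + α Σ_x Φ( Σ_i |∇u_i(x)|² )
           + β Σ_x ∇ℓ_R(x) · u(x)

where LCC is the squared local cross-correlation over 7×7×7 windows ω
(invariant to local linear intensity maps, hence robust to the phase-
dependent contrast), Φ(s) = √(s + ε²) is a total-variation-like robust
penalty that permits the sliding discontinuities of respiratory liver
motion, and the last term is a volume-preserving bias on the smoothed ROI
indicator ℓ_R. The energy is minimized coarse-to-fine over a Gaussian
pyramid (rate η = 0.75); each outer iteration linearizes the warped moving
image and solves the resulting per-voxel 3×3 systems, coupled by a
lagged-diffusivity weighted Laplacian, with red-black SOR. Registration is
two-stage: a liver-ROI stage (α = 0.001, β = 0.001, 5 outer iterations) and
a lesion-ROI refinement (α = 1.5e-4, β = 1e-4, 3 outer iterations).

**Quantification.** With Mpre, Map, Mdp the aligned phase volumes,
sub1 = Map − Mpre and sub2 = Mdp − Mpre, and the adjacent-liver value
LM = μ ± 2σ computed over liver-minus-lesion voxels (+2σ when extracting
hyperenhancement, −2σ for washout):

- `maskAPHE = [sub1 − LMsub1 > 0] ∧ [Map − LMap > 0]` — enhances
  unequivocally more than liver, and brighter than liver in AP;
- `maskWO = [sub1 > 0] ∧ ([Mdp − LMdp < 0] ∨ [sub2 − LMsub2 < 0])` — at
  least slightly enhanced in AP, and darker than the liver in DP or in the
  DP−Pre subtraction;
- `PAE = sub1 / Mpre` inside `maskAPHE` (percentage of arterial
  enhancement), `LLCR` the normalized DP hypodensity inside `maskWO`
  (lesion-to-liver contrast ratio);
- `R = V_feature / V_lesion`, the fraction of the expert lesion volume
  showing the feature — the scalar used for classification.

## Worked example

No clinical data ships with the package; the synthetic module generates
seeded digital phantoms (ellipsoidal liver, spherical lesion, HCC-like
phase contrast, parenchymal texture, smooth random respiratory-like
deformation with known ground truth):

```python
from liverquant import PhantomSpec, make_phantom, preprocess_study, \
    register_study, quantify_study, WindowSpec, dsc

study, gt = make_phantom(PhantomSpec(seed=0, max_magnitude=6.0))
prepared, _ = preprocess_study(study, window=WindowSpec(0.5, 1.0))
reg = register_study(prepared)
print("liver DSC (Pre->AP):",
      dsc(prepared.liver_masks["AP"].data, reg.warped_liver_masks["Pre"].data))

feat = quantify_study(reg.warped_pre, prepared.ap, reg.warped_dp,
                      prepared.liver_masks["AP"], prepared.lesion_masks["AP"])
print("R_APHE:", round(feat.report["R_APHE"], 3),
      "R_WO:", round(feat.report["R_WO"], 3))
```

On this phantom the run prints a liver Dice of `0.9896` after the
two-stage registration (`0.9775` after rigid pre-alignment alone), and
feature volume ratios `R_APHE: 0.969`, `R_WO: 0.994` — the lesion was
constructed with APHE and WO contrast, so nearly its whole volume is
flagged. On a noise- and deformation-free phantom the same quantification
yields `R_APHE: 0.978`, `R_WO: 1.0`.

The same steps are available from the shell:

```
liverquant phantom --seed 0 --out-dir ph/
liverquant pipeline --pre ph/pre.nii.gz --ap ph/ap.nii.gz --dp ph/dp.nii.gz \
    --liver-mask Pre=ph/liver_pre.nii.gz --liver-mask AP=ph/liver_ap.nii.gz \
    --liver-mask DP=ph/liver_dp.nii.gz \
    --lesion-mask Pre=ph/lesion_pre.nii.gz --lesion-mask AP=ph/lesion_ap.nii.gz \
    --lesion-mask DP=ph/lesion_dp.nii.gz \
    --window-center 0.5 --window-width 1.0 --out-dir run/
```

`run/report.json` then holds the volumes, ratios and adjacent-liver
statistics; `run/metrics.json` the per-stage DSC/MSD/HDD.

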