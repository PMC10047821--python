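"""Voxel-wise feature calculus on registered multiphase volumes.

Works on the common (arterial-phase) grid after registration.  Notation:
``Mpre``/``Map``/``Mdp`` are the warped Pre, the AP, and the warped DP
intensity matrices; ``sub1 = Map - Mpre`` and ``sub2 = Mdp - Mpre`` the
dynamic subtraction images; ``LM`` the adjacent-liver reference value
(mu + 2 sigma when extracting hyperenhancement, mu - 2 sigma when
extracting washout, over liver-minus-lesion voxels).

A voxel shows arterial-phase hyperenhancement (APHE) when it both enhances
unequivocally more than the liver (Esub1 = sub1 - LMsub1 > 0) and is
brighter than the liver in AP (Bap = Map - LMap > 0).  A voxel shows
washout (WO) when it enhanced at least slightly in AP (sub1 > 0) and is
darker than the liver in DP or in the DP-Pre subtraction
(Bdp = Mdp - LMdp < 0 or Wsub2 = sub2 - LMsub2 < 0).  The washout
comparisons use the "darker than" polarity; ``as_printed=True`` restores
the opposite (literal) sign convention for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MaskVolume, PhaseImage

PAE_SENTINEL = np.nan  # flagged marker for PAE at near-zero Mpre


@dataclass
class AdjacentLiverValue:
    """Reference intensity of the surrounding liver: mu +/- 2 sigma."""

    mu: float
    sigma: float
    mode: str  # "APHE" or "WO"

    def __post_init__(self) -> None:
        if self.mode not in ("APHE", "WO"):
            raise ValueError("mode must be 'APHE' or 'WO'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def lm(self) -> float:
        return self.mu + 2.0 * self.sigma if self.mode == "APHE" else self.mu - 2.0 * self.sigma


@dataclass
class SubtractionSet:
    """Subtraction images and liver-referenced difference volumes."""

    sub1: np.ndarray
    sub2: np.ndarray
    bap: np.ndarray
    bdp: np.ndarray
    esub1: np.ndarray
    wsub2: np.ndarray
    lm_ap: AdjacentLiverValue
    lm_dp: AdjacentLiverValue
    lm_sub1: AdjacentLiverValue
    lm_sub2: AdjacentLiverValue


@dataclass
class QuantReport:
    """Feature volume, lesion volume and ratio R for one feature."""

    feature: str
    v_feature_mm3: float
    v_feature_voxels: int
    v_lesion_mm3: float
    v_lesion_voxels: int
    ratio: float

    def as_dict(self) -> dict:
        return {"feature": self.feature, "V_feature_mm3": self.v_feature_mm3,
                "V_feature_voxels": self.v_feature_voxels,
                "V_lesion_mm3": self.v_lesion_mm3,
                "V_lesion_voxels": self.v_lesion_voxels, "R": self.ratio}


@dataclass
class FeatureResult:
    """Masks, value maps and volume report of the quantification run."""

    mask_aphe: MaskVolume
    mask_wo: MaskVolume
    mask_dp: MaskVolume
    mask_s: MaskVolume
    pae: np.ndarray
    llcr: np.ndarray
    report: dict = field(default_factory=dict)


def adjacent_liver_value(vol: np.ndarray, liver_mask: MaskVolume | np.ndarray,
                         lesion_mask: MaskVolume | np.ndarray, mode: str) -> AdjacentLiverValue:
    """mu/sigma of ``vol`` over liver-minus-lesion voxels (population SD)."""
    liver = liver_mask.astype_bool() if isinstance(liver_mask, MaskVolume) else np.asarray(liver_mask, dtype=bool)
    lesion = lesion_mask.astype_bool() if isinstance(lesion_mask, MaskVolume) else np.asarray(lesion_mask, dtype=bool)
    region = liver & ~lesion
    if not region.any():
        raise ValueError("liver minus lesion region is empty")
    vals = np.asarray(vol, dtype=np.float64)[region]
    return AdjacentLiverValue(mu=float(vals.mean()), sigma=float(vals.std(ddof=0)), mode=mode)


def compute_subtractions(warped_pre: PhaseImage | np.ndarray, ap: PhaseImage | np.ndarray,
                         warped_dp: PhaseImage | np.ndarray, liver_mask, lesion_mask) -> SubtractionSet:
    m_pre = np.asarray(warped_pre.data if isinstance(warped_pre, PhaseImage) else warped_pre, dtype=np.float64)
    m_ap = np.asarray(ap.data if isinstance(ap, PhaseImage) else ap, dtype=np.float64)
    m_dp = np.asarray(warped_dp.data if isinstance(warped_dp, PhaseImage) else warped_dp, dtype=np.float64)
    sub1 = m_ap - m_pre
    sub2 = m_dp - m_pre
    lm_ap = adjacent_liver_value(m_ap, liver_mask, lesion_mask, "APHE")
    lm_sub1 = adjacent_liver_value(sub1, liver_mask, lesion_mask, "APHE")
    lm_dp = adjacent_liver_value(m_dp, liver_mask, lesion_mask, "WO")
    lm_sub2 = adjacent_liver_value(sub2, liver_mask, lesion_mask, "WO")
    return SubtractionSet(sub1=sub1, sub2=sub2,
                          bap=m_ap - lm_ap.lm, bdp=m_dp - lm_dp.lm,
                          esub1=sub1 - lm_sub1.lm, wsub2=sub2 - lm_sub2.lm,
                          lm_ap=lm_ap, lm_dp=lm_dp, lm_sub1=lm_sub1, lm_sub2=lm_sub2)


def _domain(domain_mask, shape) -> np.ndarray:
    if domain_mask is None:
        return np.ones(shape, dtype=bool)
    if isinstance(domain_mask, MaskVolume):
        return domain_mask.astype_bool()
    return np.asarray(domain_mask, dtype=bool)


def aphe_mask(subs: SubtractionSet, domain_mask=None):
    """mask1 = [Esub1 > 0], mask2 = [Bap > 0], maskAPHE = mask1 AND mask2."""
    dom = _domain(domain_mask, subs.sub1.shape)
    mask1 = (subs.esub1 > 0) & dom
    mask2 = (subs.bap > 0) & dom
    return mask1, mask2, mask1 & mask2


def wo_mask(subs: SubtractionSet, domain_mask=None, as_printed: bool = False):
    """mask3 = [sub1 > 0]; mask4/mask5 flag voxels darker than the liver in
    DP or in (DP - Pre); maskWO = mask3 AND (mask4 OR mask5)."""
    dom = _domain(domain_mask, subs.sub1.shape)
    mask3 = (subs.sub1 > 0) & dom
    if as_printed:
        mask4 = (subs.bdp > 0) & dom
        mask5 = (subs.wsub2 > 0) & dom
    else:
        mask4 = (subs.bdp < 0) & dom
        mask5 = (subs.wsub2 < 0) & dom
    mask_dp = mask4 | mask5
    return mask3, mask4, mask5, mask_dp, mask3 & mask_dp


def combined_mask(mask_aphe: np.ndarray, mask_wo: np.ndarray) -> np.ndarray:
    """S = maskAPHE AND maskWO (voxels showing both features)."""
    if mask_aphe.shape != mask_wo.shape:
        raise ValueError("masks must share one grid")
    return np.asarray(mask_aphe, dtype=bool) & np.asarray(mask_wo, dtype=bool)


def pae_map(subs: SubtractionSet, warped_pre, mask_aphe: np.ndarray,
            eps_d: float = 1e-6) -> np.ndarray:
    """PAE(x) = sub1/Mpre inside maskAPHE; near-zero Mpre voxels receive a
    flagged NaN sentinel (excluded from any summary), 0 outside the mask."""
    m_pre = np.asarray(warped_pre.data if isinstance(warped_pre, PhaseImage) else warped_pre,
                       dtype=np.float64)
    out = np.zeros_like(m_pre)
    mask = np.asarray(mask_aphe, dtype=bool)
    degenerate = mask & (np.abs(m_pre) < eps_d)
    ok = mask & ~degenerate
    out[ok] = subs.sub1[ok] / m_pre[ok]
    out[degenerate] = PAE_SENTINEL
    return out


def llcr_map(subs: SubtractionSet, mask4: np.ndarray, mask5: np.ndarray,
             lm_dp: AdjacentLiverValue | None = None,
             lm_sub2: AdjacentLiverValue | None = None) -> np.ndarray:
    """LLCR0(x) = -Bdp/LMdp on mask4, else -Wsub2/LMsub2 on mask5, else 0.

    Branch priority: mask4 first.  Degenerate (near-zero) liver reference
    values are an error.
    """
    lm_dp = lm_dp or subs.lm_dp
    lm_sub2 = lm_sub2 or subs.lm_sub2
    if abs(lm_dp.lm) < 1e-6 or abs(lm_sub2.lm) < 1e-6:
        raise ValueError("degenerate adjacent-liver reference (|LM| < 1e-6)")
    out = np.zeros_like(subs.bdp)
    m4 = np.asarray(mask4, dtype=bool)
    m5 = np.asarray(mask5, dtype=bool) & ~m4
    out[m4] = -subs.bdp[m4] / lm_dp.lm
    out[m5] = -subs.wsub2[m5] / lm_sub2.lm
    return out


def volumes_and_ratio(feature_mask, lesion_mask, spacing=(1.0, 1.0, 1.0),
                      feature: str = "APHE") -> QuantReport:
    """Feature and lesion volumes (feature counted inside the lesion domain)
    and their ratio R = V_feature / V_lesion."""
    feat = _domain(feature_mask, None)
    les = _domain(lesion_mask, None)
    n_lesion = int(np.count_nonzero(les))
    if n_lesion == 0:
        raise ValueError("empty lesion mask")
    voxel = float(np.prod(spacing))
    n_feat = int(np.count_nonzero(feat & les))
    return QuantReport(feature=feature,
                       v_feature_mm3=n_feat * voxel, v_feature_voxels=n_feat,
                       v_lesion_mm3=n_lesion * voxel, v_lesion_voxels=n_lesion,
                       ratio=n_feat / n_lesion)


def quantify_study(warped_pre, ap, warped_dp, liver_mask: MaskVolume,
                   lesion_mask: MaskVolume, domain: str = "lesion",
                   as_printed: bool = False) -> FeatureResult:
    """Full feature calculus: subtractions -> location masks -> value maps
    -> volume ratios.

    ``domain`` selects where features are extracted/reported: the expert
    lesion contour (default) or the whole liver (exploratory).
    """
    subs = compute_subtractions(warped_pre, ap, warped_dp, liver_mask, lesion_mask)
    dom_mask = lesion_mask if domain == "lesion" else liver_mask
    _, _, m_aphe = aphe_mask(subs, dom_mask)
    _, m4, m5, m_dp, m_wo = wo_mask(subs, dom_mask, as_printed=as_printed)
    s = combined_mask(m_aphe, m_wo)
    pae = pae_map(subs, warped_pre, m_aphe)
    llcr = llcr_map(subs, m4, m5)
    spacing = lesion_mask.spacing
    rep_aphe = volumes_and_ratio(m_aphe, lesion_mask, spacing, "APHE")
    rep_wo = volumes_and_ratio(m_wo, lesion_mask, spacing, "WO")
    finite_pae = pae[np.asarray(m_aphe) & np.isfinite(pae)]
    finite_llcr = llcr[np.asarray(m_wo)]
    report = {
        "APHE": rep_aphe.as_dict(), "WO": rep_wo.as_dict(),
        "R_APHE": rep_aphe.ratio, "R_WO": rep_wo.ratio,
        "LM": {"ap": subs.lm_ap.lm, "dp": subs.lm_dp.lm,
               "sub1": subs.lm_sub1.lm, "sub2": subs.lm_sub2.lm},
        "liver_stats": {"mu_ap": subs.lm_ap.mu, "sigma_ap": subs.lm_ap.sigma,
                        "mu_dp": subs.lm_dp.mu, "sigma_dp": subs.lm_dp.sigma},
        "PAE_mean": float(finite_pae.mean()) if finite_pae.size else 0.0,
        "LLCR_mean": float(finite_llcr.mean()) if finite_llcr.size else 0.0,
    }
    mk = lambda arr, role="feature": MaskVolume(arr.astype(np.uint8), spacing=spacing, role=role)
    return FeatureResult(mask_aphe=mk(m_aphe), mask_wo=mk(m_wo), mask_dp=mk(m_dp),
                         mask_s=mk(s), pae=pae, llcr=llcr, report=report)
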