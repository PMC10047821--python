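"""Registration-quality metrics (DSC, MSD, HDD) and classification utilities.

Surface distances use 6-connectivity border voxels (erosion difference) and
symmetric averaging: MSD is the mean of the two directed mean
nearest-surface distances, HDD the maximum of the two directed maxima.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import roc_auc_score

from .core import MaskVolume


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, MaskVolume):
        return mask.astype_bool()
    return np.asarray(mask, dtype=bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|a n b| / (|a| + |b|), as a fraction."""
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Border voxels under 6-connectivity: mask minus its erosion."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def surface_distances(a, b, spacing=(1.0, 1.0, 1.0)) -> tuple[float, float]:
    """(MSD, HDD) in mm between the surfaces of two masks."""
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    if not a.any() or not b.any():
        raise ValueError("empty mask has no surface")
    sa = surface_voxels(a)
    sb = surface_voxels(b)
    # distance-to-surface maps (EDT of the complement of each surface set)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dist_to_b[sa]
    d_ba = dist_to_a[sb]
    msd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    hdd = max(float(d_ab.max()), float(d_ba.max()))
    return msd, hdd


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: probability that a positive outranks a negative
    (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def welch_ttest(x, y, pooled: bool = False) -> tuple[float, float]:
    """Two-sample t-test on two groups of ratios (Welch by default)."""
    res = stats.ttest_ind(np.asarray(x, dtype=np.float64),
                          np.asarray(y, dtype=np.float64), equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def evaluate_masks(a, b, spacing=(1.0, 1.0, 1.0)) -> dict:
    msd, hdd = surface_distances(a, b, spacing)
    return {"dsc": dsc(a, b), "msd_mm": msd, "hdd_mm": hdd}
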