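"""End-to-end orchestration: preprocess -> register -> quantify -> evaluate.

The pipeline is a pure function of its inputs and configuration; reruns with
identical inputs produce identical JSON reports.  Every run directory
carries a provenance record (resolved configuration, package version,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .core import Study
from .metrics import evaluate_masks, roc_auc, welch_ttest
from .preprocess import WindowSpec, preprocess_study
from .quantify import quantify_study
from .registration import RegistrationParams, register_study

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    window: WindowSpec = field(default_factory=WindowSpec)
    coarse: RegistrationParams = field(default_factory=RegistrationParams.coarse)
    fine: RegistrationParams = field(default_factory=RegistrationParams.fine)
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    crop_margin: int = 10
    rigid: bool = True
    skip_nonlinear: bool = False
    quantify_domain: str = "lesion"
    as_printed: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["target_spacing"] = list(self.target_spacing)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(path: str, obj) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def run_pipeline(study: Study, config: RunConfig | None = None,
                 out_dir: str | None = None, write_volumes: bool = False) -> dict:
    """Execute the full chain on one study.

    Returns a result dictionary with the quantification report, the
    registration metrics per stage (none / rigid / nonlinear), and
    provenance.  With ``out_dir`` set, report.json, metrics.json,
    provenance.json (and optionally the warped volumes, fields and feature
    maps as NIfTI) are written there.
    """
    config = config or RunConfig()
    t0 = time.time()
    stage = "preprocess"
    try:
        prepared_norigid, _ = preprocess_study(
            study, window=config.window, target_spacing=config.target_spacing,
            margin=config.crop_margin, rigid=False)
        prepared, prov_pre = preprocess_study(
            study, window=config.window, target_spacing=config.target_spacing,
            margin=config.crop_margin, rigid=config.rigid)

        metrics: dict = {}
        spacing = config.target_spacing
        for ph in ("Pre", "DP"):
            fx_liver = prepared.liver_masks["AP"]
            metrics[ph] = {
                "none": {"liver": evaluate_masks(prepared_norigid.liver_masks["AP"],
                                                 prepared_norigid.liver_masks[ph], spacing),
                         "lesion": evaluate_masks(prepared_norigid.lesion_masks["AP"],
                                                  prepared_norigid.lesion_masks[ph], spacing)},
                "rigid": {"liver": evaluate_masks(fx_liver, prepared.liver_masks[ph], spacing),
                          "lesion": evaluate_masks(prepared.lesion_masks["AP"],
                                                   prepared.lesion_masks[ph], spacing)},
            }

        result: dict = {"provenance": {
            "config": config.as_dict(), "config_hash": config.digest(),
            "version": __version__, "seed": config.seed,
        }}

        if config.skip_nonlinear:
            result["metrics"] = metrics
            result["report"] = None
            if out_dir:
                _dump(os.path.join(out_dir, "metrics.json"), metrics)
                _dump(os.path.join(out_dir, "provenance.json"), result["provenance"])
            return result

        stage = "register"
        reg = register_study(prepared, config.coarse, config.fine)
        for ph in ("Pre", "DP"):
            metrics[ph]["nonlinear"] = {
                "liver": evaluate_masks(prepared.liver_masks["AP"],
                                        reg.warped_liver_masks[ph], spacing),
                "lesion": evaluate_masks(prepared.lesion_masks["AP"],
                                         reg.warped_lesion_masks[ph], spacing),
            }

        stage = "quantify"
        feat = quantify_study(reg.warped_pre, prepared.ap, reg.warped_dp,
                              prepared.liver_masks["AP"], prepared.lesion_masks["AP"],
                              domain=config.quantify_domain, as_printed=config.as_printed)

        result["metrics"] = metrics
        result["report"] = feat.report
        result["runtime_s"] = round(time.time() - t0, 3)

        if out_dir:
            stage = "write"
            _dump(os.path.join(out_dir, "report.json"), feat.report)
            _dump(os.path.join(out_dir, "metrics.json"), metrics)
            _dump(os.path.join(out_dir, "provenance.json"), result["provenance"])
            if write_volumes:
                from . import io as lio
                lio.write_image(os.path.join(out_dir, "warped_pre.nii.gz"), reg.warped_pre)
                lio.write_image(os.path.join(out_dir, "warped_dp.nii.gz"), reg.warped_dp)
                lio.write_field(os.path.join(out_dir, "field_pre.nii.gz"), reg.field_pre)
                lio.write_field(os.path.join(out_dir, "field_dp.nii.gz"), reg.field_dp)
                lio.write_mask(os.path.join(out_dir, "mask_aphe.nii.gz"), feat.mask_aphe)
                lio.write_mask(os.path.join(out_dir, "mask_wo.nii.gz"), feat.mask_wo)
                lio.write_mask(os.path.join(out_dir, "mask_s.nii.gz"), feat.mask_s)
                lio._write_array(os.path.join(out_dir, "pae.nii.gz"),
                                 feat.pae.astype(np.float32), spacing)
                lio._write_array(os.path.join(out_dir, "llcr.nii.gz"),
                                 feat.llcr.astype(np.float32), spacing)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc


def classify_by_ratio(ratios_a, ratios_b, pooled: bool = False) -> dict:
    """Two-group comparison of feature volume ratios: t-test + rank AUC.

    Group a is taken as the positive class for the AUC.
    """
    a = np.asarray(ratios_a, dtype=np.float64)
    b = np.asarray(ratios_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    t, p = welch_ttest(a, b, pooled=pooled)
    scores = np.concatenate([a, b])
    labels = np.concatenate([np.ones(a.size, dtype=int), np.zeros(b.size, dtype=int)])
    return {"t_statistic": t, "p_value": p, "auc": roc_auc(scores, labels)}
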