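"""End-to-end orchestration of the diagnostic chain.

The full pipeline mirrors the modular diagnostic framework: locate the eye
regions and scale bar on the face frame, segment the ocular structures in
the primary and gaze positions, run the quantitative retraction and
motility rules, crop the inflammation-bearing structures and classify them.

Two execution modes share one report schema:

* **oracle mode** feeds ground-truth label masks straight into the
  landmark/diagnosis stages, isolating the analytic rules from model error;
* **model mode** predicts the masks with a trained segmentation network
  (and, when classifier heads are supplied, adds inflammation labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnosis import compile_eye_report
from .errors import TedEyeError
from .geometry import calibrate_from_scalebar, crop_structures
from .metrics import (
    diagnostic_metrics,
    prevalence_summary,
    regression_metrics,
    segmentation_metrics,
)
from .types import Calibration, EyeReport, GAZE_FRAMES, LabelMask


@dataclass
class RunConfig:
    """Seeds, paths and mode switches for a pipeline run; YAML-serializable."""

    seed: int = 0
    mode: str = "oracle"  # "oracle" | "model"
    data_dir: str = "."
    output_dir: str = "runs"
    seg_checkpoint: str | None = None
    cls_checkpoints: dict = field(default_factory=dict)
    calibration_mm_per_px: float | None = None
    extra: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


def diagnose_eye(eye_id: str, eye_side: str, mask_primary: LabelMask,
                 gaze_masks: dict | None, calib: Calibration) -> EyeReport:
    """Oracle-mode single-eye diagnosis from ground-truth (or predicted)
    masks; thin wrapper kept for symmetry with model mode."""
    return compile_eye_report(eye_id, eye_side, mask_primary, gaze_masks, calib)


def run_full_diagnosis(face_image: np.ndarray, face_mask: LabelMask,
                       eye_sides: dict | None = None,
                       seg_model=None,
                       cls_heads: dict | None = None,
                       mode: str = "oracle",
                       oracle_masks: dict | None = None,
                       calibration: Calibration | None = None) -> dict:
    """Run the pipeline on one face frame.

    In model mode ``seg_model`` predicts each 512-crop's structures; in
    oracle mode ``oracle_masks`` must map side -> primary LabelMask.  The
    scale bar is always measured from the face frame unless an explicit
    calibration is supplied.  Returns ``{side: report dict}`` plus the
    calibration actually used.
    """
    from .geometry import locate_and_crop

    crops = locate_and_crop(face_image, face_mask)
    calib = calibration or calibrate_from_scalebar(crops["scale_strip"])

    eye_sides = eye_sides or {"left": "left", "right": "right"}
    reports = {"calibration": {"mm_per_px": calib.mm_per_px,
                               "division_px": calib.division_px}}
    for side in ("left", "right"):
        crop, offset = crops[side]
        if mode == "oracle":
            if not oracle_masks or side not in oracle_masks:
                raise TedEyeError(f"oracle mode needs a mask for side {side!r}")
            mask = oracle_masks[side]
        else:
            if seg_model is None:
                raise TedEyeError(
                    "model mode needs a trained segmentation checkpoint"
                )
            pred = seg_model.predict(crop[None])[0]
            mask = LabelMask(grid=pred, ontology="primary5")
        report = compile_eye_report(side, eye_sides[side], mask, None, calib)
        entry = report.to_dict()
        entry["crop_offset"] = list(offset)
        if cls_heads:
            from .nn.clsnet import classify_structures

            struct_crops = crop_structures(
                crop, mask, calib,
                out_size=next(iter(cls_heads.values())).config.input_size,
            )
            preds = classify_structures(struct_crops, cls_heads)
            entry["inflammation"] = {
                s: (None if p is None
                    else {"probabilities": p.probabilities,
                          "decisions": p.decisions})
                for s, p in preds.items()
            }
        reports[side] = entry
    return reports


def evaluate_cohort(reports: dict[str, EyeReport], manifest: pd.DataFrame,
                    pred_masks: dict | None = None,
                    true_masks: dict | None = None) -> dict:
    """Score a set of per-eye reports against the cohort manifest.

    Emits the four metric families: segmentation overlap (when predicted
    masks are supplied), diagnostic accuracy for the retraction and
    motility calls, regression error for the recovered millimetre
    quantities, and the prevalence table of the manifest.
    """
    ids = list(manifest["eye_id"])
    missing = [i for i in ids if i not in reports]
    if missing:
        raise TedEyeError(f"missing reports for eyes: {missing[:10]}")

    bundle: dict = {}

    if pred_masks is not None:
        if true_masks is None:
            raise TedEyeError("segmentation scoring needs true masks as well")
        per_eye = [
            segmentation_metrics(pred_masks[i], true_masks[i]) for i in ids
        ]
        mpas = [m["mpa"] for m in per_eye if m["mpa"] is not None]
        bundle["segmentation"] = {
            "mean_mpa": float(np.mean(mpas)) if mpas else None,
        }

    m = manifest.set_index("eye_id")
    pred_upper = [reports[i].retraction.upper_flag for i in ids]
    pred_lower = [reports[i].retraction.lower_flag for i in ids]
    true_upper = [m.loc[i, "upper_retraction_mm"] > 0 for i in ids]
    true_lower = [m.loc[i, "lower_retraction_mm"] > 0 for i in ids]
    bundle["diagnostics"] = {
        "upper_retraction": diagnostic_metrics(pred_upper, true_upper),
        "lower_retraction": diagnostic_metrics(pred_lower, true_lower),
    }

    pred_mot, true_mot = [], []
    for i in ids:
        rep = reports[i]
        if not rep.motility:
            continue
        by_dir = {r.direction: r.disorder for r in rep.motility}
        for d, call in by_dir.items():
            pred_mot.append(call)
            true_mot.append(bool(m.loc[i, f"disorder_{d}"]))
    if pred_mot:
        bundle["diagnostics"]["eye_movement_disorder"] = diagnostic_metrics(
            pred_mot, true_mot
        )

    est_up = [reports[i].retraction.upper_show_mm for i in ids]
    tru_up = [m.loc[i, "true_upper_show_mm"] for i in ids]
    est_dn = [reports[i].retraction.lower_show_mm for i in ids]
    tru_dn = [m.loc[i, "true_lower_show_mm"] for i in ids]
    bundle["regression"] = {
        "upper_show_mm": regression_metrics(est_up, tru_up),
        "lower_show_mm": regression_metrics(est_dn, tru_dn),
    }

    denominator = len(ids)
    symptoms = [c for c in (
        "redness_eyelid", "swelling_eyelid", "redness_conj",
        "swelling_conj", "swelling_lcp",
    ) if c in manifest.columns]
    bundle["prevalence"] = prevalence_summary(
        manifest, {s: denominator for s in symptoms}
    )
    return bundle


def oracle_reports_for_cohort(cohort_dir, manifest: pd.DataFrame,
                              with_gaze: bool = False) -> dict:
    """Run oracle-mode diagnosis on every eye of a generated cohort."""
    from . import io as tio

    cohort_dir = Path(cohort_dir)
    reports = {}
    for row in manifest.itertuples():
        calib = Calibration.from_mm_per_px(row.mm_per_px)
        mask = tio.read_mask(cohort_dir / "masks" / f"{row.eye_id}.png", "primary5")
        gaze_masks = None
        if with_gaze:
            gaze_masks = {
                f: tio.read_mask(
                    cohort_dir / "masks" / f"{row.eye_id}_{f}.png", "gaze4"
                )
                for f in GAZE_FRAMES
            }
        reports[row.eye_id] = compile_eye_report(
            row.eye_id, row.side, mask, gaze_masks, calib
        )
    return reports
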