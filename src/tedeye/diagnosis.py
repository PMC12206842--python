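"""Rule-based quantitative diagnosis of eyelid retraction and eye-movement
disorder from landmarks and a pixel calibration.

The rules translate the clinical criteria into pixel/millimetre thresholds:

1. Vertical gaze (up/down): the iris should clear the line joining the
   canthus surrogates; an overlap of less than 20 px with that line is
   normal, >= 20 px is a movement disorder.
2. Medial gaze: the horizontal distance from the pupil's inner margin to the
   medial canthus, minus the primary-frame distance from the punctum
   reference to the medial canthus, must be negative (the pupil passes the
   punctum) — >= 0 px is a disorder.
3. Lateral gaze: the residual scleral gap between the iris outer margin and
   the lateral canthus must be <= 0 px; a positive gap is a disorder.
4. Upper retraction: with the cornea reasonably exposed, D_down - D_up
   (lower minus upper margin distance to the pupil center) must exceed
   1 mm; smaller or equal values flag upper-lid retraction.
5. Lower retraction: the lower lid margin must not sit below the inferior
   limbus; visible sclera below the limbus flags lower-lid retraction.

Scleral show above/below the limbus at the pupil column drives the
four-level retraction category (upper only / both / lower only / normal).
"""

from __future__ import annotations

import math

import numpy as np

from .errors import TedEyeError
from .geometry import extract_landmarks
from .synthetic import measure_is_disorder
from .types import (
    Calibration,
    EyeReport,
    GAZE_FRAMES,
    LabelMask,
    Landmarks,
    MARGIN_DIFF_THRESHOLD_MM,
    MotilityResult,
    RetractionResult,
    resolve_direction,
)

#: Guard for rule 4: fraction of the expected iris disc that must be visible
#: for the "cornea relatively well exposed" condition.
IRIS_EXPOSURE_FRACTION = 0.8

_RULE_IDS = {"up": "rule1", "down": "rule1", "medial": "rule2", "lateral": "rule3"}


def _visible_iris_fraction(mask: LabelMask, landmarks: Landmarks) -> float:
    """Visible iris+pupil pixels over the area of the disc implied by the
    iris width (the horizontal diameter is rarely occluded by the lids)."""
    iris_px = np.count_nonzero(
        (mask.grid == mask.class_index("iris"))
        | (mask.grid == mask.class_index("pupil"))
    )
    radius = abs(landmarks.iris_outer[1] - landmarks.iris_inner[1]) / 2.0
    if radius <= 0:
        return 0.0
    return iris_px / (math.pi * radius**2)


def diagnose_retraction(mask_primary: LabelMask, landmarks: Landmarks,
                        calib: Calibration) -> RetractionResult:
    """Apply the retraction rules to primary-position landmarks."""
    if calib is None:
        raise TedEyeError("calibration is required for millimetre quantities")
    if landmarks.ontology != "primary5":
        raise ValueError("retraction diagnosis requires primary-position landmarks")
    mmpp = calib.mm_per_px

    pupil_row = landmarks.pupil_center[0]
    d_up = (pupil_row - landmarks.upper_margin_row) * mmpp
    d_down = (landmarks.lower_margin_row - pupil_row) * mmpp
    upper_show = max(0.0, landmarks.iris_top[0] - landmarks.upper_margin_row) * mmpp
    lower_show = max(0.0, landmarks.lower_margin_row - landmarks.iris_bottom[0]) * mmpp
    margin_diff = d_down - d_up

    category = {
        (False, False): "normal",
        (True, False): "upper_only",
        (False, True): "lower_only",
        (True, True): "both",
    }[(upper_show > 0, lower_show > 0)]

    cornea_exposed = (
        upper_show > 0
        or _visible_iris_fraction(mask_primary, landmarks) >= IRIS_EXPOSURE_FRACTION
    )
    upper_flag = upper_show > 0 or (
        cornea_exposed and margin_diff <= MARGIN_DIFF_THRESHOLD_MM
    )
    lower_flag = lower_show > 0

    return RetractionResult(
        D_up=d_up,
        D_down=d_down,
        upper_show_mm=upper_show,
        lower_show_mm=lower_show,
        margin_diff_mm=margin_diff,
        category=category,
        upper_flag=upper_flag,
        lower_flag=lower_flag,
    )


def _canthal_line_overlap(mask: LabelMask, landmarks: Landmarks, below: bool) -> float:
    """Perpendicular extent of iris pixels past the canthal line, >= 0."""
    mr, mc = landmarks.medial_canthus
    lr, lc = landmarks.lateral_canthus
    if mc == lc:
        raise TedEyeError("degenerate canthal line (canthus columns coincide)")
    slope = (lr - mr) / (lc - mc)
    cos_theta = 1.0 / math.sqrt(1.0 + slope**2)
    iris = np.nonzero(
        (mask.grid == mask.class_index("iris"))
        | (mask.grid == mask.class_index("pupil"))
    )
    rows = iris[0].astype(np.float64)
    cols = iris[1].astype(np.float64)
    line_rows = mr + slope * (cols - mc)
    signed = (rows - line_rows) if below else (line_rows - rows)
    return max(0.0, float(signed.max()) * cos_theta)


def diagnose_gaze(direction: str, eye_side: str, mask_gaze: LabelMask,
                  landmarks_gaze: Landmarks,
                  landmarks_primary: Landmarks | None,
                  calib: Calibration,
                  gaze_frame: str | None = None) -> MotilityResult:
    """Apply the motility rule for one gaze direction."""
    if calib is None:
        raise TedEyeError("calibration is required for millimetre quantities")
    if direction not in _RULE_IDS:
        raise TedEyeError(f"unknown gaze direction {direction!r}")

    if direction in ("up", "down"):
        measure = _canthal_line_overlap(
            mask_gaze, landmarks_gaze, below=(direction == "up")
        )
    elif direction == "medial":
        if landmarks_primary is None or landmarks_primary.punctum_ref is None:
            raise TedEyeError(
                "medial-gaze diagnosis needs primary-frame landmarks with a "
                "punctum reference"
            )
        gaze_dist = abs(
            landmarks_gaze.pupil_inner[1] - landmarks_gaze.medial_canthus[1]
        )
        primary_dist = abs(
            landmarks_primary.punctum_ref[1] - landmarks_primary.medial_canthus[1]
        )
        measure = float(gaze_dist - primary_dist)
    else:  # lateral
        lateral_sign = -1 if eye_side == "right" else +1
        gap = lateral_sign * (
            landmarks_gaze.lateral_canthus[1] - landmarks_gaze.iris_outer[1]
        )
        measure = max(0.0, float(gap))

    return MotilityResult(
        direction=direction,
        gaze_frame=gaze_frame or direction,
        measure_px=measure,
        measure_mm=measure * calib.mm_per_px,
        disorder=measure_is_disorder(direction, measure),
        rule_id=_RULE_IDS[direction],
    )


def compile_eye_report(eye_id: str, eye_side: str,
                       mask_primary: LabelMask,
                       gaze_masks: dict[str, LabelMask] | None,
                       calib: Calibration) -> EyeReport:
    """Run landmark extraction and both diagnoses for one eye.

    ``gaze_masks`` maps gaze-frame names (subset of up/down/left/right) to
    their masks; absent frames yield no motility entry.
    """
    lm_primary = extract_landmarks(mask_primary, eye_side)
    retraction = diagnose_retraction(mask_primary, lm_primary, calib)

    motility = []
    for frame in GAZE_FRAMES:
        if not gaze_masks or frame not in gaze_masks:
            continue
        mask_g = gaze_masks[frame]
        lm_g = extract_landmarks(mask_g, eye_side)
        direction = resolve_direction(eye_side, frame)
        motility.append(
            diagnose_gaze(
                direction, eye_side, mask_g, lm_g, lm_primary, calib,
                gaze_frame=frame,
            )
        )

    return EyeReport(
        eye_id=eye_id,
        eye_side=eye_side,
        mm_per_px=calib.mm_per_px,
        retraction=retraction,
        motility=motility,
    )
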