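"""Scale-bar calibration, eye-region cropping and landmark extraction.

These are the analytic front-end stages of the diagnostic pipeline: convert
the rendered (or annotated) scale bar into a mm-per-pixel factor, cut
fixed-size eye crops out of the face frame, and derive the reference points
that the quantitative rules consume from a label mask.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .errors import CalibrationError, LocalizationError, MissingStructureError
from .types import (
    Calibration,
    LabelMask,
    Landmarks,
    PRIMARY5,
    FACE4,
)

CROP_SIZE = 512
#: Eyelid crop band height when no calibration is available, pixels (= 2 mm
#: at the reference 0.1 mm/px scale).
DEFAULT_LID_BAND_PX = 20.0
EYELID_BAND_MM = 2.0


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def calibrate_from_scalebar(scale_region: np.ndarray) -> Calibration:
    """Measure the 5 mm division length of an alternating black/white strip.

    ``scale_region`` is an image strip (RGB or grayscale) containing at
    least two divisions along its long axis.  The strip is averaged across
    its short axis, binarized at the mid-intensity, and the division length
    is the median run length of the interior runs (the two end runs may be
    truncated by the crop and are discarded).
    """
    arr = np.asarray(scale_region, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError("scale_region must be a 2-D strip or an RGB image")
    if arr.shape[0] < arr.shape[1]:
        arr = arr.T
    profile = arr.mean(axis=1)

    lo, hi = profile.min(), profile.max()
    if hi - lo < 20:
        raise CalibrationError(
            "scale strip has no black/white contrast (uniform intensity)"
        )
    binary = profile > (lo + hi) / 2.0
    transitions = np.nonzero(np.diff(binary.astype(np.int8)))[0]
    if len(transitions) < 2:
        raise CalibrationError(
            f"only {len(transitions)} intensity transitions found; need >= 2 "
            "alternating divisions"
        )
    run_lengths = np.diff(transitions).astype(np.float64)
    division_px = float(np.median(run_lengths))
    if division_px <= 0:
        raise CalibrationError("degenerate division length")
    calib = Calibration(division_px=division_px)
    calib.validate()
    return calib


# --------------------------------------------------------------------------
# Face-frame cropping
# --------------------------------------------------------------------------

def _bbox(mask: np.ndarray):
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return rows[0], cols[0], rows[-1] + 1, cols[-1] + 1


def _crop_centered(image: np.ndarray, center: tuple[int, int], size: int):
    """Fixed-size crop about a center, zero-padded beyond the canvas."""
    r0 = int(round(center[0])) - size // 2
    c0 = int(round(center[1])) - size // 2
    out_shape = (size, size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    r1, c1 = r0 + size, c0 + size
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, image.shape[0]), min(c1, image.shape[1])
    out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out, (r0, c0)


def locate_and_crop(face_image: np.ndarray, face_mask: LabelMask,
                    crop_size: int = CROP_SIZE) -> dict:
    """Cut per-eye crops and the scale strip out of a face frame.

    Returns ``{"left": (crop, offset), "right": (crop, offset),
    "scale_strip": strip_image}`` where ``offset`` is the (row, col) of the
    crop's top-left corner in face coordinates, so that
    ``face_point = offset + crop_point``.
    """
    if face_mask.ontology != FACE4:
        raise ValueError(f"expected a {FACE4!r} mask, got {face_mask.ontology!r}")
    out = {}
    for side in ("left", "right"):
        region = face_mask.grid == face_mask.class_index(f"{side}_eye")
        if not region.any():
            raise LocalizationError(side)
        r0, c0, r1, c1 = _bbox(region)
        center = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)
        out[side] = _crop_centered(face_image, center, crop_size)
    scale = face_mask.grid == face_mask.class_index("scale")
    if not scale.any():
        raise LocalizationError("scale")
    r0, c0, r1, c1 = _bbox(scale)
    out["scale_strip"] = face_image[r0:r1, c0:c1]
    return out


# --------------------------------------------------------------------------
# Landmarks
# --------------------------------------------------------------------------

def _extreme_pixel(coords: np.ndarray, axis: int, largest: bool) -> tuple[int, int]:
    """Extreme point along an axis.

    Ties among equally-extreme pixels are resolved deterministically: for
    column extremes (canthi, inner/outer margins) by smallest row then
    column; for row extremes (top/bottom of a region, whose tie set can be
    a wide flat arc) by the median column, which stays on the region's
    axis of symmetry.
    """
    vals = coords[:, axis]
    target = vals.max() if largest else vals.min()
    cand = coords[vals == target]
    if axis == 1:
        order = np.lexsort((cand[:, 1], cand[:, 0]))
        return tuple(int(v) for v in cand[order[0]])
    cols = np.sort(cand[:, 1])
    med = cols[len(cols) // 2]
    row = cand[cand[:, 1] == med][:, 0].min()
    return int(row), int(med)


def extract_landmarks(mask: LabelMask, eye_side: str) -> Landmarks:
    """Derive the diagnostic reference points from a label mask.

    The pupil center is the rounded centroid of the pupil class.  Aperture
    margins at the pupil column are medians over a +-3-column band, which
    resists single-column raster noise.  Canthus surrogates and the punctum
    reference follow the clinical-standard conversion: medial canthus =
    medial-most caruncle-plica pixel (medial-most scleral pixel in gaze
    frames, which lack that class), lateral canthus = lateral-most scleral
    pixel, punctum = intersection of the caruncle-plica's lateral boundary
    with the lower eyelid margin.
    """
    grid = mask.grid
    required = ["sclera", "iris", "pupil"]
    if mask.ontology == PRIMARY5:
        required.append("lcp")
    coords = {}
    for name in required:
        px = mask.pixels_of(name)
        if len(px) == 0:
            raise MissingStructureError(name)
        coords[name] = px

    pupil = coords["pupil"]
    pupil_center = (
        int(round(pupil[:, 0].mean())),
        int(round(pupil[:, 1].mean())),
    )

    aperture = grid > 0
    pc = pupil_center[1]
    band = range(max(0, pc - 3), min(grid.shape[1], pc + 4))
    top_rows, bot_rows = [], []
    for c in band:
        col_rows = np.nonzero(aperture[:, c])[0]
        if len(col_rows):
            top_rows.append(col_rows[0])
            bot_rows.append(col_rows[-1])
    if not top_rows:
        raise MissingStructureError("aperture")
    upper_margin_row = float(np.median(top_rows))
    lower_margin_row = float(np.median(bot_rows))

    medial_largest = eye_side == "right"  # medial canthus sits noseward
    if mask.ontology == PRIMARY5:
        medial_src = coords["lcp"]
        lateral_src = coords["sclera"]
    else:
        # Gaze frames lack the caruncle-plica class, and in extreme gaze the
        # iris can occlude a corner of the fissure entirely; the aperture
        # extreme is the corner itself whether or not sclera shows there.
        aperture_px = np.argwhere(aperture)
        medial_src = lateral_src = aperture_px
    medial_canthus = _extreme_pixel(medial_src, axis=1, largest=medial_largest)
    lateral_canthus = _extreme_pixel(lateral_src, axis=1, largest=not medial_largest)

    punctum_ref = None
    if mask.ontology == PRIMARY5:
        lcp = coords["lcp"]
        lat_col = lcp[:, 1].min() if medial_largest else lcp[:, 1].max()
        on_col = lcp[lcp[:, 1] == lat_col]
        punctum_ref = (int(on_col[:, 0].max()), int(lat_col))

    iris = np.concatenate([coords["iris"], coords["pupil"]])
    lm = Landmarks(
        pupil_center=pupil_center,
        medial_canthus=medial_canthus,
        lateral_canthus=lateral_canthus,
        punctum_ref=punctum_ref,
        iris_top=_extreme_pixel(iris, axis=0, largest=False),
        iris_bottom=_extreme_pixel(iris, axis=0, largest=True),
        iris_inner=_extreme_pixel(iris, axis=1, largest=medial_largest),
        iris_outer=_extreme_pixel(iris, axis=1, largest=not medial_largest),
        pupil_inner=_extreme_pixel(pupil, axis=1, largest=medial_largest),
        pupil_outer=_extreme_pixel(pupil, axis=1, largest=not medial_largest),
        upper_margin_row=upper_margin_row,
        lower_margin_row=lower_margin_row,
        eye_side=eye_side,
        ontology=mask.ontology,
    )
    return lm


# --------------------------------------------------------------------------
# Structure crops for the inflammation classifier
# --------------------------------------------------------------------------

def _pad_bbox(r0, c0, r1, c1, shape, frac=0.1):
    dr = int(round((r1 - r0) * frac))
    dc = int(round((c1 - c0) * frac))
    return (
        max(0, r0 - dr),
        max(0, c0 - dc),
        min(shape[0], r1 + dr),
        min(shape[1], c1 + dc),
    )


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    return np.asarray(
        Image.fromarray(img).resize((size, size), Image.BILINEAR)
    )


def crop_structures(image: np.ndarray, mask: LabelMask,
                    calibration: Calibration | None = None,
                    out_size: int = 256) -> dict:
    """Cut the eyelid, conjunctiva and caruncle-plica crops for classification.

    The eyelid crop stacks two bands of fixed physical height (2 mm when a
    calibration is supplied, 20 px otherwise) taken just outside the upper
    and lower aperture margins.  The conjunctiva and caruncle-plica crops are
    the bounding boxes of their classes.  All crops are padded by 10% and
    resized to ``out_size``.
    """
    if mask.ontology != PRIMARY5:
        raise ValueError("structure crops require a primary-position mask")
    grid = mask.grid
    band_px = (
        EYELID_BAND_MM / calibration.mm_per_px if calibration else DEFAULT_LID_BAND_PX
    )
    band_px = max(2, int(round(band_px)))

    aperture = grid > 0
    if not aperture.any():
        raise MissingStructureError("aperture")
    r0, c0, r1, c1 = _bbox(aperture)

    up0 = max(0, r0 - band_px)
    lo1 = min(grid.shape[0], r1 + band_px)
    upper_band = image[up0:r0, c0:c1]
    lower_band = image[r1:lo1, c0:c1]
    if upper_band.size == 0 and lower_band.size == 0:
        raise MissingStructureError("eyelid")
    eyelid = np.concatenate([b for b in (upper_band, lower_band) if b.size], axis=0)

    crops = {"eyelid": _resize(eyelid, out_size)}
    for name, key in (("conjunctiva", "sclera"), ("lcp", "lcp")):
        region = grid == mask.class_index(key)
        if not region.any():
            raise MissingStructureError(key)
        b = _pad_bbox(*_bbox(region), grid.shape)
        crops[name] = _resize(image[b[0]:b[2], b[1]:b[3]], out_size)
    return crops
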