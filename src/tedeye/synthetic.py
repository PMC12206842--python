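"""Seeded parametric generator of eye images, pixel-exact label masks and
known ground truth.

The generator emulates a standardized ocular photography setup: head-fixed
frontal eye crops in the primary position and in four extreme gaze positions,
plus a face-level canvas carrying a side-mounted scale bar of alternating
5 mm black/white divisions.  Both the rendered image and the label mask are
rasterized from the same analytic shapes, so the mask is pixel-exact ground
truth by construction, and all truth quantities (eyelid distances, gaze
deficits) are computed from the parameters rather than from the raster.

Geometry model
--------------
The palpebral aperture is bounded by two parabolic eyelid arcs that meet at
the canthi, with apexes on the pupil column.  Iris and pupil are concentric
discs translated by a gaze offset.  The caruncle-plica (LCP) occupies a
vertical wedge of the aperture at the medial corner.  Eyelid retraction
raises (lowers) the upper (lower) arc so that the margin sits the requested
number of millimetres beyond the corresponding limbus.  Gaze frames translate
the discs by a direction-specific physiologic full excursion minus the
requested deficit; the eyelids stay fixed, as the head and lids are
constrained by the acquisition device.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance
from scipy import ndimage

from .errors import CalibrationError, DegenerateApertureError
from .types import (
    ANATOMICAL_DIRECTIONS,
    GAZE_FRAMES,
    GAZE4,
    PRIMARY5,
    FACE4,
    SCALE_DIVISION_MM,
    VERTICAL_OVERLAP_THRESHOLD_PX,
    EyeGeometryParams,
    LabelMask,
    PathologyParams,
    SyntheticTruth,
    as_uint8_image,
    resolve_direction,
)

# Physiologic-excursion bookkeeping (pixels).  Full medial excursion carries
# the pupil inner margin MEDIAL_SLACK_PX past the punctum reference; full
# lateral excursion carries the iris outer margin LATERAL_SLACK_PX past the
# lateral canthus.  Vertical full excursion brings the iris edge exactly to
# the canthal line.  Only deficits relative to these constants are
# diagnostic.
MEDIAL_SLACK_PX = 10.0
LATERAL_SLACK_PX = 3.0

#: Gaze-rule disorder thresholds expressed on the measure for each direction.
MEASURE_THRESHOLDS = {
    "up": ("ge", float(VERTICAL_OVERLAP_THRESHOLD_PX)),
    "down": ("ge", float(VERTICAL_OVERLAP_THRESHOLD_PX)),
    "medial": ("ge", 0.0),
    "lateral": ("gt", 0.0),
}


def measure_is_disorder(direction: str, measure_px: float) -> bool:
    """Apply the per-direction motility threshold to a measure in pixels."""
    kind, thr = MEASURE_THRESHOLDS[direction]
    return measure_px >= thr if kind == "ge" else measure_px > thr


def derive_seed(seed: int, *key: int) -> int:
    """Derive a reproducible child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# Analytic shapes
# --------------------------------------------------------------------------

def _effective_apexes(geom: EyeGeometryParams, path: PathologyParams) -> tuple[float, float]:
    """Eyelid apex distances after applying retraction, in pixels."""
    s = 1.0 / geom.mm_per_px
    a_up = geom.upper_lid_apex
    a_dn = geom.lower_lid_apex
    if path.upper_retraction_mm > 0:
        a_up = geom.iris_radius + path.upper_retraction_mm * s
    if path.lower_retraction_mm > 0:
        a_dn = geom.iris_radius + path.lower_retraction_mm * s
    return a_up, a_dn


def _arc_rows(geom: EyeGeometryParams, a_up: float, a_dn: float, col):
    """Rows of the upper/lower lid arcs at the given column(s)."""
    r0, c0 = geom.pupil_center
    w = geom.half_fissure_px
    u = (np.asarray(col, dtype=np.float64) - c0) / w
    shape = 1.0 - u**2
    return r0 - a_up * shape, r0 + a_dn * shape


def full_excursion_px(geom: EyeGeometryParams, direction: str) -> float:
    """Physiologic full excursion of the iris center for one direction."""
    w = geom.half_fissure_px
    if direction in ("up", "down"):
        return geom.iris_radius
    if direction == "medial":
        return (w - geom.pupil_radius) - geom.lcp_width + MEDIAL_SLACK_PX
    if direction == "lateral":
        return (w - geom.iris_radius) + LATERAL_SLACK_PX
    raise ValueError(f"unknown direction {direction!r}")


def gaze_measure_px(geom: EyeGeometryParams, direction: str, deficit_px: float) -> float:
    """Analytic value of the motility measure for a given deficit."""
    if direction in ("up", "down"):
        return float(deficit_px)
    if direction == "medial":
        return float(deficit_px) - MEDIAL_SLACK_PX
    if direction == "lateral":
        return max(0.0, float(deficit_px) - LATERAL_SLACK_PX)
    raise ValueError(f"unknown direction {direction!r}")


def deficit_for_measure(geom: EyeGeometryParams, direction: str, measure_px: float) -> float:
    """Invert :func:`gaze_measure_px`: deficit producing a desired measure."""
    if direction in ("up", "down"):
        return float(measure_px)
    if direction == "medial":
        return float(measure_px) + MEDIAL_SLACK_PX
    if direction == "lateral":
        return float(measure_px) + LATERAL_SLACK_PX
    raise ValueError(f"unknown direction {direction!r}")


def _gaze_offset_px(geom: EyeGeometryParams, direction: str, deficit_px: float):
    """(d_row, d_col) iris translation for a gaze direction with a deficit."""
    e = full_excursion_px(geom, direction) - float(deficit_px)
    if direction == "up":
        return (-e, 0.0)
    if direction == "down":
        return (e, 0.0)
    if direction == "medial":
        return (0.0, geom.medial_sign * e)
    return (0.0, -geom.medial_sign * e)


# --------------------------------------------------------------------------
# Rasterization
# --------------------------------------------------------------------------

def _region_masks(geom: EyeGeometryParams, a_up: float, a_dn: float,
                  iris_center: tuple[float, float], ontology: str) -> dict:
    rows, cols = geom.image_size
    r0, c0 = geom.pupil_center
    w = geom.half_fissure_px
    rr = np.arange(rows, dtype=np.float64)[:, None]
    cc = np.arange(cols, dtype=np.float64)[None, :]
    u = (cc - c0) / w
    shape = 1.0 - u**2
    arc_up = r0 - a_up * shape
    arc_dn = r0 + a_dn * shape
    aperture = (np.abs(u) <= 1.0) & (rr >= arc_up) & (rr <= arc_dn)
    if not aperture.any():
        raise DegenerateApertureError(a_up, a_dn)

    ri, ci = iris_center
    d2 = (rr - ri) ** 2 + (cc - ci) ** 2
    iris = d2 <= geom.iris_radius**2
    pupil = d2 <= geom.pupil_radius**2

    c_med = c0 + geom.medial_sign * w
    t = geom.medial_sign * (c_med - cc)
    lcp = (t >= 0.0) & (t <= geom.lcp_width)

    regions = {
        "aperture": aperture,
        "sclera": aperture & ~iris,
        "iris": aperture & iris & ~pupil,
        "pupil": aperture & pupil,
        "arc_up": arc_up,
        "arc_dn": arc_dn,
        "u": u,
    }
    if ontology == PRIMARY5:
        lcp_vis = aperture & lcp & ~iris
        regions["lcp"] = lcp_vis
        regions["sclera"] = regions["sclera"] & ~lcp_vis
    return regions


def _mask_from_regions(geom: EyeGeometryParams, regions: dict, ontology: str) -> LabelMask:
    grid = np.zeros(geom.image_size, dtype=np.uint8)
    grid[regions["sclera"]] = 1
    grid[regions["iris"]] = 2
    grid[regions["pupil"]] = 3
    if ontology == PRIMARY5:
        grid[regions["lcp"]] = 4
    return LabelMask(grid=grid, ontology=ontology)


_IRIS_PALETTE = np.array(
    [
        [115.0, 75.0, 45.0],   # brown
        [140.0, 100.0, 55.0],  # hazel
        [95.0, 115.0, 135.0],  # blue-gray
        [105.0, 120.0, 85.0],  # green
    ]
)


def _render_image(geom: EyeGeometryParams, path: PathologyParams, regions: dict,
                  rng: np.random.Generator) -> np.ndarray:
    """Paint the regions with noisy but class-separable appearance."""
    rows, cols = geom.image_size
    img = np.empty((rows, cols, 3), dtype=np.float64)

    # skin background with smooth mottling
    base_skin = np.array([205.0, 170.0, 150.0]) + rng.uniform(-8, 8, size=3)
    mottle = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), max(2, rows // 64))
    img[:] = base_skin
    img += 12.0 * mottle[..., None]

    rr = np.arange(rows, dtype=np.float64)[:, None]
    cc = np.arange(cols, dtype=np.float64)[None, :]
    ri, ci = geom.pupil_center
    off_r, off_c = geom.gaze_offset  # iris center actually passed via regions
    arc_up, arc_dn, u = regions["arc_up"], regions["arc_dn"], regions["u"]

    # eyelid bands (2 mm outside each margin) carry the lid inflammation cues
    band_h = 2.0 / geom.mm_per_px
    in_span = np.abs(u) <= 1.05
    upper_band = in_span & (rr < arc_up) & (rr >= arc_up - band_h)
    lower_band = in_span & (rr > arc_dn) & (rr <= arc_dn + band_h)
    lid_band = upper_band | lower_band
    img[lid_band] += np.array([6.0, -4.0, -4.0])  # faint natural lid tint
    if path.redness_eyelid > 0:
        img[lid_band] += path.redness_eyelid * np.array([55.0, -28.0, -28.0])
    if path.swelling_eyelid > 0:
        bump = ndimage.gaussian_filter(lid_band.astype(np.float64), band_h / 2.0)
        img += path.swelling_eyelid * 38.0 * bump[..., None]

    # sclera
    sclera_color = np.array([246.0, 241.0, 235.0])
    img[regions["sclera"]] = sclera_color
    if path.redness_conj > 0:
        img[regions["sclera"]] += path.redness_conj * np.array([4.0, -60.0, -60.0])
    vessels = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), 1.5)
    img[..., 1][regions["sclera"]] -= 6.0 * np.abs(vessels[regions["sclera"]])
    img[..., 2][regions["sclera"]] -= 6.0 * np.abs(vessels[regions["sclera"]])
    if path.swelling_conj > 0:
        near_lid = regions["sclera"] & (
            (rr <= arc_up + band_h) | (rr >= arc_dn - band_h)
        )
        bump = ndimage.gaussian_filter(near_lid.astype(np.float64), band_h / 3.0)
        img += path.swelling_conj * 30.0 * bump[..., None]

    # iris with limbal darkening and radial fibres
    iris_center_row = ri + off_r
    iris_center_col = ci + off_c
    d = np.sqrt((rr - iris_center_row) ** 2 + (cc - iris_center_col) ** 2)
    iris_color = _IRIS_PALETTE[rng.integers(len(_IRIS_PALETTE))] + rng.uniform(-10, 10, 3)
    rim = np.clip(d / max(geom.iris_radius, 1.0), 0.0, 1.0)
    shade = (0.55 + 0.45 * (1.0 - rim**3))[..., None]
    theta = np.arctan2(rr - iris_center_row, cc - iris_center_col)
    fibres = 10.0 * np.sin(theta * rng.integers(9, 14)) * (rim > 0.35)
    iris_px = regions["iris"]
    img[iris_px] = (iris_color[None, :] * shade[iris_px]) + fibres[iris_px, None]

    # pupil
    img[regions["pupil"]] = np.array([24.0, 20.0, 20.0])

    # caruncle-plica
    if "lcp" in regions:
        lcp_color = np.array([226.0, 132.0, 122.0])
        img[regions["lcp"]] = lcp_color
        if path.swelling_lcp > 0:
            img[regions["lcp"]] += path.swelling_lcp * np.array([24.0, 36.0, 30.0])

    # specular glint near the pupil margin
    glint_r = iris_center_row - 0.4 * geom.pupil_radius
    glint_c = iris_center_col + 0.4 * geom.pupil_radius
    glint = (rr - glint_r) ** 2 + (cc - glint_c) ** 2 <= (0.22 * geom.pupil_radius) ** 2
    img[glint & regions["aperture"]] = 252.0

    img += rng.normal(0, 5.0, img.shape)
    return as_uint8_image(img)


def _analytic_truth(geom: EyeGeometryParams, path: PathologyParams,
                    a_up: float, a_dn: float,
                    iris_center: tuple[float, float],
                    overlaps: dict | None = None) -> SyntheticTruth:
    mmpp = geom.mm_per_px
    r0, c0 = geom.pupil_center
    ri, ci = iris_center
    w = geom.half_fissure_px
    arc_up_p, arc_dn_p = _arc_rows(geom, a_up, a_dn, ci)

    d_up_px = ri - float(arc_up_p)
    d_dn_px = float(arc_dn_p) - ri
    upper_show_px = max(0.0, (ri - geom.iris_radius) - float(arc_up_p))
    lower_show_px = max(0.0, float(arc_dn_p) - (ri + geom.iris_radius))

    upper = path.upper_retraction_mm > 0
    lower = path.lower_retraction_mm > 0
    category = {
        (False, False): "normal",
        (True, False): "upper_only",
        (False, True): "lower_only",
        (True, True): "both",
    }[(upper, lower)]

    overlaps = dict(overlaps or {})
    disorder = {
        d: measure_is_disorder(d, m) for d, m in overlaps.items()
    }

    c_med = c0 + geom.medial_sign * w
    c_lat = c0 - geom.medial_sign * w
    punctum_col = c_med - geom.medial_sign * geom.lcp_width
    _, punctum_row = _arc_rows(geom, a_up, a_dn, punctum_col)

    landmarks = {
        "pupil_center": (float(ri), float(ci)),
        "medial_canthus": (float(r0), float(c_med)),
        "lateral_canthus": (float(r0), float(c_lat)),
        "punctum_ref": (float(punctum_row), float(punctum_col)),
        "upper_margin_row": float(arc_up_p),
        "lower_margin_row": float(arc_dn_p),
        "iris_top": (max(float(arc_up_p), ri - geom.iris_radius), float(ci)),
        "iris_bottom": (min(float(arc_dn_p), ri + geom.iris_radius), float(ci)),
    }

    return SyntheticTruth(
        true_D_up=d_up_px * mmpp,
        true_D_down=d_dn_px * mmpp,
        true_retraction_category=category,
        true_upper_show_mm=upper_show_px * mmpp,
        true_lower_show_mm=lower_show_px * mmpp,
        true_margin_diff_mm=(d_dn_px - d_up_px) * mmpp,
        true_overlap=overlaps,
        true_disorder=disorder,
        labels=path.inflammation_flags(),
        true_landmarks=landmarks,
    )


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------

def generate_eye(geom: EyeGeometryParams, path: PathologyParams, seed: int,
                 ontology: str = PRIMARY5):
    """Render one eye and its pixel-exact mask plus analytic ground truth.

    Returns ``(image, mask, truth)`` where ``image`` is (rows, cols, 3)
    uint8, ``mask`` a :class:`LabelMask` and ``truth`` a
    :class:`SyntheticTruth`.  Identical parameters and seed reproduce the
    outputs bit for bit.
    """
    geom.validate()
    path.validate()
    a_up, a_dn = _effective_apexes(geom, path)
    if a_up + a_dn <= 2:
        raise DegenerateApertureError(a_up, a_dn)
    iris_center = (
        geom.pupil_center[0] + geom.gaze_offset[0],
        geom.pupil_center[1] + geom.gaze_offset[1],
    )
    regions = _region_masks(geom, a_up, a_dn, iris_center, ontology)
    mask = _mask_from_regions(geom, regions, ontology)
    rng = np.random.default_rng(seed)
    img = _render_image(geom, path, regions, rng)
    overlaps = {
        d: gaze_measure_px(geom, d, path.gaze_limit.get(d, 0.0))
        for d in ANATOMICAL_DIRECTIONS
    }
    truth = _analytic_truth(geom, path, a_up, a_dn, iris_center, overlaps)
    return img, mask, truth


def generate_gaze_series(geom: EyeGeometryParams, path: PathologyParams, seed: int):
    """Head-fixed five-frame series: primary plus four extreme gazes.

    The primary frame uses the full structure ontology (with caruncle-plica);
    gaze frames label sclera/iris/pupil only.  Each gaze frame translates the
    iris/pupil by the physiologic full excursion minus the requested deficit;
    the eyelid arcs are identical across frames.
    """
    geom.validate()
    path.validate()
    series = {}
    series["primary"] = generate_eye(geom, path, derive_seed(seed, 0), PRIMARY5)
    for i, frame in enumerate(GAZE_FRAMES):
        direction = resolve_direction(geom.eye_side, frame)
        deficit = float(path.gaze_limit.get(direction, 0.0))
        offset = _gaze_offset_px(geom, direction, deficit)
        geom_f = dataclasses.replace(geom, gaze_offset=offset)
        img, mask, truth = generate_eye(geom_f, path, derive_seed(seed, i + 1), GAZE4)
        for cls in ("sclera", "iris", "pupil"):
            if not (mask.grid == mask.class_index(cls)).any():
                from .errors import MissingStructureError

                raise MissingStructureError(
                    f"{cls} (fully occluded in {frame!r} gaze; widen the lids "
                    "or the pupil)"
                )
        series[frame] = (img, mask, truth)
    return series


def _face_layout(canvas_size: tuple[int, int], tile: int, mm_per_px: float) -> dict:
    rows, cols = canvas_size
    strip_w = 24
    margin = 30
    division_px = SCALE_DIVISION_MM / mm_per_px
    strip_c0 = cols - margin - strip_w
    top = (rows - tile) // 2
    right_c0 = margin
    left_c0 = strip_c0 - margin - tile
    return {
        "top": top,
        "right_tile": (top, right_c0),
        "left_tile": (top, left_c0),
        "strip": (0, strip_c0, rows, strip_c0 + strip_w),
        "division_px": division_px,
    }


def generate_face(geom_left: EyeGeometryParams, geom_right: EyeGeometryParams,
                  seed: int, canvas_size: tuple[int, int] = (700, 1300)):
    """Compose both eye tiles and the scale bar on a face-level canvas.

    The subject's right eye appears on the viewer's left.  The scale bar is a
    vertical strip of alternating black/white 5 mm divisions along the right
    edge of the canvas, mirroring a ruler mounted on the side of the
    acquisition device.  Returns ``(canvas, localization mask)`` with mask
    classes {0 bg, 1 left eye, 2 right eye, 3 scale}.
    """
    if abs(geom_left.mm_per_px - geom_right.mm_per_px) > 1e-12:
        raise ValueError("both eyes must share mm_per_px for a single scale bar")
    mm_per_px = geom_left.mm_per_px
    tile = geom_left.image_size[0]
    if geom_right.image_size != geom_left.image_size:
        raise ValueError("eye tiles must share image_size")
    layout = _face_layout(canvas_size, tile, mm_per_px)
    if layout["division_px"] < 4:
        raise CalibrationError(
            f"scale-bar division {layout['division_px']:.1f} px is below the "
            "4 px rendering minimum"
        )
    rows, cols = canvas_size
    if layout["top"] < 0 or layout["left_tile"][1] < layout["right_tile"][1] + tile:
        raise ValueError("eye tiles do not fit the canvas without overlap")

    rng = np.random.default_rng(derive_seed(seed, 99))
    canvas = np.empty((rows, cols, 3), dtype=np.float64)
    canvas[:] = np.array([205.0, 170.0, 150.0])
    mottle = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), 8)
    canvas += 12.0 * mottle[..., None]
    canvas = as_uint8_image(canvas)

    nopath = PathologyParams()
    img_r, _, _ = generate_eye(geom_right, nopath, derive_seed(seed, 0), PRIMARY5)
    img_l, _, _ = generate_eye(geom_left, nopath, derive_seed(seed, 1), PRIMARY5)

    mask = np.zeros((rows, cols), dtype=np.uint8)
    tr, cr = layout["right_tile"]
    tl, cl = layout["left_tile"]
    canvas[tr:tr + tile, cr:cr + tile] = img_r
    canvas[tl:tl + tile, cl:cl + tile] = img_l
    mask[tr:tr + tile, cr:cr + tile] = 2
    mask[tl:tl + tile, cl:cl + tile] = 1

    r0, c0, r1, c1 = layout["strip"]
    div = layout["division_px"]
    rr = np.arange(rows)
    cell = (np.floor(rr / div).astype(int) % 2)
    strip_col = np.where(cell == 0, 15, 240).astype(np.uint8)
    canvas[r0:r1, c0:c1, :] = strip_col[r0:r1, None, None]
    mask[r0:r1, c0:c1] = 3

    return canvas, LabelMask(grid=mask, ontology=FACE4)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

#: Per-symptom prevalences used as the default study conditions for cohorts,
#: chosen to match the composition of a TED clinic population (upper/lower
#: retraction among primary-position eyes, motility disorder among gaze
#: series, and the five image-visible inflammation signs).
DEFAULT_PREVALENCE = {
    "upper_retraction": 0.36,
    "lower_retraction": 0.42,
    "eye_movement_disorder": 0.32,
    "redness_eyelid": 0.26,
    "swelling_eyelid": 0.67,
    "redness_conj": 0.65,
    "swelling_conj": 0.18,
    "swelling_lcp": 0.37,
}


def sample_eye_params(rng: np.random.Generator,
                      prevalence: dict,
                      image_size: tuple[int, int] = (512, 512),
                      mm_per_px: float = 0.1):
    """Draw one eye's geometry and pathology from the cohort distribution.

    Geometry varies within normal anatomical ranges while keeping healthy
    eyes clear of the diagnostic thresholds: the lower-minus-upper margin
    difference stays above 1.3 mm and both lids overlap their limbus, so a
    healthy draw can never sit closer than ~0.3 mm to a retraction rule.
    Retraction magnitudes are uniform in [0.3, 3.0] mm; motility deficits
    place the measured quantity 5-30 px beyond its threshold.
    """
    s = 1.0 / mm_per_px
    rows, cols = image_size
    side = "left" if rng.random() < 0.5 else "right"

    # Ranges keep every structure annotatable in every frame: with static
    # lids, a pupil of indoor-photograph size (diameter 4.4-5.2 mm) stays
    # partially visible even at full vertical excursion.
    iris_mm = rng.uniform(5.7, 5.9)
    a_up_mm = rng.uniform(4.0, 4.15)
    a_dn_mm = min(a_up_mm + rng.uniform(1.4, 1.6), iris_mm - 0.15)
    jitter = (rng.uniform(-1.0, 1.0), rng.uniform(-0.05, 0.05) * s)

    geom = EyeGeometryParams(
        image_size=image_size,
        pupil_center=(rows / 2.0 + jitter[0], cols / 2.0 + jitter[1]),
        iris_radius=iris_mm * s,
        pupil_radius=rng.uniform(2.2, 2.6) * s,
        upper_lid_apex=a_up_mm * s,
        lower_lid_apex=a_dn_mm * s,
        lid_curvature=rng.uniform(2.3, 2.5),
        lcp_width=rng.uniform(2.7, 3.3) * s,
        gaze_offset=(0.0, rng.uniform(-2.0, 2.0) * mm_per_px * s * 0.1),
        eye_side=side,
        mm_per_px=mm_per_px,
    )

    path = PathologyParams()
    if rng.random() < prevalence.get("upper_retraction", 0.0):
        path.upper_retraction_mm = rng.uniform(0.3, 3.0)
    if rng.random() < prevalence.get("lower_retraction", 0.0):
        path.lower_retraction_mm = rng.uniform(0.3, 3.0)
    if rng.random() < prevalence.get("eye_movement_disorder", 0.0):
        direction = ANATOMICAL_DIRECTIONS[rng.integers(4)]
        margin = rng.uniform(5.0, 30.0)
        kind, thr = MEASURE_THRESHOLDS[direction]
        path.gaze_limit = {
            direction: deficit_for_measure(geom, direction, thr + margin)
        }
    for name in PathologyParams.INFLAMMATION_LABELS:
        if rng.random() < prevalence.get(name, 0.0):
            setattr(path, name, float(rng.uniform(0.5, 1.0)))
    return geom, path


def _truth_row(eye_id: str, geom: EyeGeometryParams, path: PathologyParams,
               truth: SyntheticTruth, split: str) -> dict:
    row = {
        "eye_id": eye_id,
        "side": geom.eye_side,
        "split": split,
        "mm_per_px": geom.mm_per_px,
        "true_D_up_mm": truth.true_D_up,
        "true_D_down_mm": truth.true_D_down,
        "retraction_category": truth.true_retraction_category,
        "upper_retraction_mm": path.upper_retraction_mm,
        "lower_retraction_mm": path.lower_retraction_mm,
        "true_upper_show_mm": truth.true_upper_show_mm,
        "true_lower_show_mm": truth.true_lower_show_mm,
        "true_margin_diff_mm": truth.true_margin_diff_mm,
    }
    for d in ANATOMICAL_DIRECTIONS:
        row[f"overlap_{d}_px"] = truth.true_overlap.get(d, 0.0)
        row[f"disorder_{d}"] = int(truth.true_disorder.get(d, False))
    row["motility_disorder"] = int(any(truth.true_disorder.values()))
    for name, flag in truth.labels.items():
        row[name] = int(flag)
    return row


def assign_splits(n: int, rng: np.random.Generator) -> list[str]:
    """Random 8:1:1 train/val/test assignment."""
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    perm = rng.permutation(n)
    out = [""] * n
    for pos, lab in zip(perm, labels):
        out[pos] = lab
    return out


def sample_cohort(n: int, prevalence: dict | None, seed: int,
                  image_size: tuple[int, int] = (512, 512),
                  mm_per_px: float = 0.1):
    """Draw a seeded cohort in memory: per-eye ``(geom, path, split)``.

    The per-eye parameter draws and split assignment are identical to what
    :func:`generate_cohort` writes to disk.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prevalence = DEFAULT_PREVALENCE if prevalence is None else prevalence
    for k, v in prevalence.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"prevalence[{k!r}] must lie in [0, 1]")
    splits = assign_splits(n, np.random.default_rng(derive_seed(seed, 777)))
    out = []
    for i in range(n):
        rng = np.random.default_rng(derive_seed(seed, i, 0))
        geom, path = sample_eye_params(rng, prevalence, image_size, mm_per_px)
        out.append((geom, path, splits[i]))
    return out


def generate_cohort(n: int, prevalence: dict | None, seed: int, out_dir,
                    image_size: tuple[int, int] = (512, 512),
                    mm_per_px: float = 0.1,
                    include_gaze: bool = False) -> pd.DataFrame:
    """Write a seeded cohort of eyes (images, masks, manifest) to disk.

    One manifest row per eye with all truth fields and an 8:1:1
    train/val/test split.  With ``include_gaze`` the four gaze frames of each
    eye are written as well (gaze ontology, no caruncle-plica class).
    Re-running with the same arguments reproduces every file byte for byte.
    """
    from . import io as tio

    sampled = sample_cohort(n, prevalence, seed, image_size, mm_per_px)

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, (geom, path, split) in enumerate(sampled):
        eye_id = f"eye{i:04d}"
        if include_gaze:
            series = generate_gaze_series(geom, path, derive_seed(seed, i, 1))
            img, mask, truth = series["primary"]
            for frame in GAZE_FRAMES:
                fimg, fmask, _ = series[frame]
                tio.write_image(img_dir / f"{eye_id}_{frame}.png", fimg)
                tio.write_mask(mask_dir / f"{eye_id}_{frame}.png", fmask)
        else:
            img, mask, truth = generate_eye(geom, path, derive_seed(seed, i, 1))
        tio.write_image(img_dir / f"{eye_id}.png", img)
        tio.write_mask(mask_dir / f"{eye_id}.png", mask)
        rows.append(_truth_row(eye_id, geom, path, truth, split))

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# --------------------------------------------------------------------------
# Augmentation
# --------------------------------------------------------------------------

def _enhance(img: np.ndarray, enhancer, factor: float) -> np.ndarray:
    return np.asarray(enhancer(Image.fromarray(img)).enhance(factor))


def augment_sample(image: np.ndarray, mask: LabelMask, seed: int):
    """Photometric and geometric augmentations of one (image, mask) pair.

    Photometric transforms (brightness 1.5, contrast alpha 1.5 / beta 0,
    3x3 grey dilation and erosion) alter the image only.  Geometric
    transforms (horizontal flip; rotation drawn uniformly in (-20, +20)
    degrees, applied with probability 0.5) are applied identically to image
    and mask, the mask with nearest-neighbour resampling.
    """
    if image.shape[:2] != mask.grid.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.grid.shape} sizes differ"
        )
    rng = np.random.default_rng(seed)
    out = []

    flipped = image[:, ::-1].copy()
    out.append((flipped, LabelMask(mask.grid[:, ::-1].copy(), mask.ontology)))

    out.append((_enhance(image, ImageEnhance.Brightness, 1.5), mask))
    out.append((_enhance(image, ImageEnhance.Contrast, 1.5), mask))

    dil = np.stack(
        [ndimage.grey_dilation(image[..., k], size=(3, 3)) for k in range(3)], axis=-1
    )
    ero = np.stack(
        [ndimage.grey_erosion(image[..., k], size=(3, 3)) for k in range(3)], axis=-1
    )
    out.append((dil, mask))
    out.append((ero, mask))

    if rng.random() < 0.5:
        angle = rng.uniform(-20.0, 20.0)
        rot_img = ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
        rot_mask = ndimage.rotate(mask.grid, angle, reshape=False, order=0, mode="constant")
        out.append((as_uint8_image(rot_img), LabelMask(rot_mask, mask.ontology)))
    return out
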