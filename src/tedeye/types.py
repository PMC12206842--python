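"""Domain types shared across the pipeline.

Conventions
-----------
* Coordinates are 0-based ``(row, col)`` with row increasing downward.
  "Vertical" distances are row differences, "horizontal" are column
  differences.
* Physical lengths are millimetres; raster lengths are pixels.  The bridge
  between the two is :class:`Calibration`, derived from the 5 mm divisions of
  the rendered scale bar.
* Label masks use small integer class indices; see :data:`ONTOLOGIES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

# --------------------------------------------------------------------------
# Label ontologies
# --------------------------------------------------------------------------

#: Primary-position masks label all four ocular structures.
PRIMARY5 = "primary5"
#: Gaze-position masks label sclera/iris/pupil only (the caruncle-plica region
#: is not annotated in gaze frames).
GAZE4 = "gaze4"
#: Face-level localization masks label the two eye regions and the scale bar.
FACE4 = "face4"

ONTOLOGIES = {
    PRIMARY5: {0: "background", 1: "sclera", 2: "iris", 3: "pupil", 4: "lcp"},
    GAZE4: {0: "background", 1: "sclera", 2: "iris", 3: "pupil"},
    FACE4: {0: "background", 1: "left_eye", 2: "right_eye", 3: "scale"},
}

CLASS_INDEX = {
    PRIMARY5: {v: k for k, v in ONTOLOGIES[PRIMARY5].items()},
    GAZE4: {v: k for k, v in ONTOLOGIES[GAZE4].items()},
    FACE4: {v: k for k, v in ONTOLOGIES[FACE4].items()},
}

#: Physical length of one scale-bar division (alternating black/white cells).
SCALE_DIVISION_MM = 5.0

#: Gaze directions in subject-anatomical terms used by the motility rules.
ANATOMICAL_DIRECTIONS = ("up", "down", "medial", "lateral")
#: Gaze frame keys in subject-egocentric terms ("left" = subject looks left).
GAZE_FRAMES = ("up", "down", "left", "right")

#: Pixel thresholds of the motility rules.  Vertical gaze: iris overlap with
#: the canthal line below 20 px is normal.  Medial gaze: the pupil inner
#: margin must pass the punctum reference (difference < 0 px normal).
#: Lateral gaze: no residual scleral gap (<= 0 px normal).
VERTICAL_OVERLAP_THRESHOLD_PX = 20
#: Rule-(4) margin: D_down - D_up must exceed 1 mm in a normal eye.
MARGIN_DIFF_THRESHOLD_MM = 1.0

RETRACTION_CATEGORIES = ("normal", "upper_only", "lower_only", "both")


def resolve_direction(eye_side: str, gaze_frame: str) -> str:
    """Map a subject-egocentric gaze frame to an anatomical direction.

    A right eye looking to the subject's left adducts (medial gaze); a left
    eye looking left abducts (lateral gaze).  Vertical frames map to
    themselves.
    """
    if gaze_frame in ("up", "down"):
        return gaze_frame
    if gaze_frame not in ("left", "right"):
        raise ValueError(f"unknown gaze frame {gaze_frame!r}")
    if eye_side not in ("left", "right"):
        raise ValueError(f"unknown eye side {eye_side!r}")
    return "medial" if gaze_frame != eye_side else "lateral"


@dataclass
class LabelMask:
    """Per-pixel class grid plus the ontology naming its indices."""

    grid: np.ndarray  # (rows, cols) of small ints
    ontology: str

    def validate(self) -> None:
        if self.ontology not in ONTOLOGIES:
            raise ValueError(f"unknown ontology {self.ontology!r}")
        classes = set(ONTOLOGIES[self.ontology])
        present = set(np.unique(self.grid).tolist())
        if not present <= classes:
            raise ValueError(
                f"mask contains classes {sorted(present - classes)} outside "
                f"ontology {self.ontology!r}"
            )

    @property
    def n_classes(self) -> int:
        return len(ONTOLOGIES[self.ontology])

    def class_index(self, name: str) -> int:
        return CLASS_INDEX[self.ontology][name]

    def pixels_of(self, name: str) -> np.ndarray:
        """(k, 2) array of (row, col) coordinates of one class, row-major."""
        rows, cols = np.nonzero(self.grid == self.class_index(name))
        return np.stack([rows, cols], axis=1)


# --------------------------------------------------------------------------
# Generator parameter types
# --------------------------------------------------------------------------

@dataclass
class EyeGeometryParams:
    """Parametric description of one eye in raster coordinates.

    The palpebral aperture is bounded by two parabolic eyelid arcs that meet
    at the canthi; the apex of each arc sits on the pupil column.  The iris
    and pupil are concentric discs translated by ``gaze_offset``.
    """

    image_size: tuple[int, int] = (512, 512)
    pupil_center: tuple[float, float] = (256.0, 256.0)
    iris_radius: float = 58.0
    pupil_radius: float = 18.0
    #: Signed pixels from pupil-center row up to the upper-lid apex (D_up).
    upper_lid_apex: float = 43.0
    #: Signed pixels from pupil-center row down to the lower-lid apex (D_down).
    lower_lid_apex: float = 56.0
    #: Half palpebral-fissure width in units of the iris radius.
    lid_curvature: float = 2.4
    #: Width of the caruncle-plica wedge at the medial corner, pixels.
    lcp_width: float = 30.0
    #: (d_row, d_col) translation applied to the iris/pupil discs.
    gaze_offset: tuple[float, float] = (0.0, 0.0)
    eye_side: str = "left"
    mm_per_px: float = 0.1

    @property
    def half_fissure_px(self) -> float:
        return self.lid_curvature * self.iris_radius

    @property
    def medial_sign(self) -> int:
        """Column direction (+1/-1) pointing from pupil toward the nose."""
        return +1 if self.eye_side == "right" else -1

    def validate(self) -> None:
        if self.pupil_radius >= self.iris_radius:
            raise ValueError(
                f"pupil_radius {self.pupil_radius} must be < iris_radius {self.iris_radius}"
            )
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.eye_side not in ("left", "right"):
            raise ValueError(f"eye_side must be 'left' or 'right', got {self.eye_side!r}")
        if self.upper_lid_apex + self.lower_lid_apex <= 2:
            from .errors import DegenerateApertureError

            raise DegenerateApertureError(self.upper_lid_apex, self.lower_lid_apex)


def default_geometry(
    image_size: tuple[int, int] = (512, 512),
    mm_per_px: float = 0.1,
    eye_side: str = "left",
) -> EyeGeometryParams:
    """Anatomically plausible adult defaults, expressed at a given scale.

    Iris radius 5.8 mm, pupil 1.8 mm, upper lid apex 4.3 mm above and lower
    apex 5.6 mm below the pupil center (so the lids cover both limbi and the
    lower-minus-upper margin difference is 1.3 mm, comfortably normal).
    """
    s = 1.0 / mm_per_px  # px per mm
    rows, cols = image_size
    return EyeGeometryParams(
        image_size=image_size,
        pupil_center=(rows / 2.0, cols / 2.0),
        iris_radius=5.8 * s,
        pupil_radius=1.8 * s,
        upper_lid_apex=4.3 * s,
        lower_lid_apex=5.6 * s,
        lid_curvature=2.4,
        lcp_width=3.0 * s,
        gaze_offset=(0.0, 0.0),
        eye_side=eye_side,
        mm_per_px=mm_per_px,
    )


@dataclass
class PathologyParams:
    """Disease burden applied on top of the base geometry."""

    #: mm of scleral show above the superior limbus (0 = none).
    upper_retraction_mm: float = 0.0
    #: mm of scleral show below the inferior limbus.
    lower_retraction_mm: float = 0.0
    #: direction -> pixels of excursion deficit.
    gaze_limit: dict = field(default_factory=dict)
    redness_eyelid: float = 0.0
    swelling_eyelid: float = 0.0
    redness_conj: float = 0.0
    swelling_conj: float = 0.0
    swelling_lcp: float = 0.0

    INFLAMMATION_LABELS = (
        "redness_eyelid",
        "swelling_eyelid",
        "redness_conj",
        "swelling_conj",
        "swelling_lcp",
    )

    def validate(self) -> None:
        if self.upper_retraction_mm < 0 or self.lower_retraction_mm < 0:
            raise ValueError("retraction distances must be >= 0")
        for d, v in self.gaze_limit.items():
            if d not in ANATOMICAL_DIRECTIONS:
                raise ValueError(f"unknown gaze direction {d!r}")
            if v < 0:
                raise ValueError(f"gaze deficit for {d!r} must be >= 0")
        for name in self.INFLAMMATION_LABELS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} intensity must lie in [0, 1], got {v}")

    def inflammation_flags(self) -> dict:
        return {name: bool(getattr(self, name) > 0) for name in self.INFLAMMATION_LABELS}


@dataclass
class SyntheticTruth:
    """Generator-known ground truth for parameter-recovery testing."""

    true_D_up: float  # mm
    true_D_down: float  # mm
    true_retraction_category: str
    true_upper_show_mm: float
    true_lower_show_mm: float
    true_margin_diff_mm: float
    #: direction -> analytic value of the motility measure, pixels (signed).
    true_overlap: dict
    #: direction -> ground-truth disorder call.
    true_disorder: dict
    #: per-structure inflammation flags.
    labels: dict
    #: analytic landmark coordinates in (row, col); used by recovery tests.
    true_landmarks: dict

    def validate(self) -> None:
        if self.true_retraction_category not in RETRACTION_CATEGORIES:
            raise ValueError(f"bad category {self.true_retraction_category!r}")
        if self.true_D_up < 0 or self.true_D_down < 0:
            raise ValueError("D_up/D_down must be >= 0")


# --------------------------------------------------------------------------
# Measurement types
# --------------------------------------------------------------------------

@dataclass
class Calibration:
    """Pixel-to-millimetre conversion from the 5 mm scale-bar divisions."""

    division_px: float
    division_mm: float = SCALE_DIVISION_MM

    @property
    def mm_per_px(self) -> float:
        return self.division_mm / self.division_px

    def validate(self) -> None:
        if self.division_px <= 0:
            raise ValueError("division_px must be positive")

    @classmethod
    def from_mm_per_px(cls, mm_per_px: float) -> "Calibration":
        return cls(division_px=SCALE_DIVISION_MM / mm_per_px)


@dataclass
class Landmarks:
    """Reference points extracted from a label mask.

    The medial canthus surrogate is the medial-most caruncle-plica pixel in
    primary frames (medial-most scleral pixel in gaze frames, which lack that
    class); the lateral canthus is the lateral-most scleral pixel.  The
    punctum reference is the intersection of the caruncle-plica's lateral
    boundary with the lower eyelid margin and exists only in primary frames.
    """

    pupil_center: tuple[int, int]
    medial_canthus: tuple[int, int]
    lateral_canthus: tuple[int, int]
    punctum_ref: Optional[tuple[int, int]]
    iris_top: tuple[int, int]
    iris_bottom: tuple[int, int]
    iris_inner: tuple[int, int]
    iris_outer: tuple[int, int]
    pupil_inner: tuple[int, int]
    pupil_outer: tuple[int, int]
    upper_margin_row: float
    lower_margin_row: float
    eye_side: str
    ontology: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RetractionResult:
    D_up: float  # mm
    D_down: float  # mm
    upper_show_mm: float
    lower_show_mm: float
    margin_diff_mm: float
    category: str
    upper_flag: bool
    lower_flag: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MotilityResult:
    direction: str
    gaze_frame: str
    measure_px: float
    measure_mm: float
    disorder: bool
    rule_id: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EyeReport:
    eye_id: str
    eye_side: str
    mm_per_px: float
    retraction: Optional[RetractionResult]
    motility: list

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "eye_side": self.eye_side,
            "mm_per_px": self.mm_per_px,
            "retraction": self.retraction.to_dict() if self.retraction else None,
            "motility": [m.to_dict() for m in self.motility],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeReport":
        ret = RetractionResult(**d["retraction"]) if d.get("retraction") else None
        mot = [MotilityResult(**m) for m in d.get("motility", [])]
        return cls(
            eye_id=d["eye_id"],
            eye_side=d["eye_side"],
            mm_per_px=d["mm_per_px"],
            retraction=ret,
            motility=mot,
        )


def as_uint8_image(arr: np.ndarray) -> np.ndarray:
    """Clip a float image to [0, 255] and convert to uint8."""
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)
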