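"""Calibration, cropping, landmark extraction and structure crops."""

import dataclasses

import numpy as np
import pytest

from tedeye import geometry as geo
from tedeye import synthetic as syn
from tedeye.errors import CalibrationError, LocalizationError, MissingStructureError
from tedeye.types import (
    Calibration,
    LabelMask,
    PathologyParams,
    default_geometry,
)


def render_strip(division_px: float, length: int = 600, width: int = 20):
    rows = np.arange(length)
    cell = (np.floor(rows / division_px).astype(int) % 2)
    col = np.where(cell == 0, 10, 245).astype(np.uint8)
    return np.repeat(col[:, None], width, axis=1)


class TestCalibration:
    def test_known_division_recovered(self):
        calib = geo.calibrate_from_scalebar(render_strip(50))
        assert calib.mm_per_px == pytest.approx(0.1, rel=0.02)

    def test_uniform_strip_fails(self):
        with pytest.raises(CalibrationError):
            geo.calibrate_from_scalebar(np.full((200, 20), 128, dtype=np.uint8))

    def test_doubling_scale_halves_mm_per_px(self):
        a = geo.calibrate_from_scalebar(render_strip(40))
        b = geo.calibrate_from_scalebar(render_strip(80, length=900))
        assert b.mm_per_px == pytest.approx(a.mm_per_px / 2, rel=0.02)

    @pytest.mark.parametrize("mm_per_px", [0.05, 0.08, 0.1, 0.15, 0.2])
    def test_render_calibrate_roundtrip_within_2pct(self, mm_per_px):
        division = 5.0 / mm_per_px
        calib = geo.calibrate_from_scalebar(render_strip(division, length=800))
        assert calib.mm_per_px == pytest.approx(mm_per_px, rel=0.02)

    def test_roundtrip_through_face_canvas(self):
        gl = default_geometry(eye_side="left")
        gr = default_geometry(eye_side="right")
        img, mask = syn.generate_face(gl, gr, seed=11)
        crops = geo.locate_and_crop(img, mask)
        calib = geo.calibrate_from_scalebar(crops["scale_strip"])
        assert calib.mm_per_px == pytest.approx(0.1, rel=0.02)


@pytest.fixture(scope="module")
def face():
    gl = default_geometry(eye_side="left")
    gr = default_geometry(eye_side="right")
    return syn.generate_face(gl, gr, seed=12)


class TestLocateAndCrop:

    def test_crops_are_512(self, face):
        crops = geo.locate_and_crop(*face)
        for side in ("left", "right"):
            assert crops[side][0].shape == (512, 512, 3)

    def test_corner_eye_padded(self, face):
        img, mask = face
        # move the left-eye region to the canvas corner
        grid = np.zeros_like(mask.grid)
        grid[:100, :100] = 1
        grid[mask.grid == 2] = 2
        grid[mask.grid == 3] = 3
        crops = geo.locate_and_crop(img, LabelMask(grid, "face4"))
        assert crops["left"][0].shape == (512, 512, 3)

    def test_offset_bookkeeping(self, face):
        img, mask = face
        crops = geo.locate_and_crop(img, mask)
        crop, (r0, c0) = crops["right"]
        rr, cc = 100, 200
        assert np.array_equal(crop[rr, cc], img[r0 + rr, c0 + cc])

    def test_missing_eye_raises_with_side(self, face):
        img, mask = face
        grid = mask.grid.copy()
        grid[grid == 1] = 0
        with pytest.raises(LocalizationError) as err:
            geo.locate_and_crop(img, LabelMask(grid, "face4"))
        assert err.value.side == "left"


class TestLandmarks:
    def test_pupil_center_within_1px(self, healthy_eye, geom):
        lm = geo.extract_landmarks(healthy_eye[1], geom.eye_side)
        assert abs(lm.pupil_center[0] - geom.pupil_center[0]) <= 1
        assert abs(lm.pupil_center[1] - geom.pupil_center[1]) <= 1

    def test_missing_pupil_raises(self, healthy_eye):
        grid = healthy_eye[1].grid.copy()
        grid[grid == 3] = 2
        with pytest.raises(MissingStructureError) as err:
            geo.extract_landmarks(LabelMask(grid, "primary5"), "left")
        assert err.value.structure == "pupil"

    def test_gaze_mask_has_no_punctum(self, geom):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=13)
        lm = geo.extract_landmarks(series["up"][1], geom.eye_side)
        assert lm.punctum_ref is None
        assert lm.medial_canthus is not None
        assert lm.iris_top is not None

    def test_translation_equivariance(self, healthy_eye, geom):
        mask = healthy_eye[1]
        lm0 = geo.extract_landmarks(mask, geom.eye_side)
        dr, dc = 7, -11
        shifted = np.zeros_like(mask.grid)
        shifted[7:, :501] = mask.grid[:-7, 11:]
        lm1 = geo.extract_landmarks(LabelMask(shifted, "primary5"), geom.eye_side)
        for name in ("pupil_center", "medial_canthus", "lateral_canthus",
                     "punctum_ref", "iris_top", "iris_bottom"):
            a, b = getattr(lm0, name), getattr(lm1, name)
            assert b[0] - a[0] == dr and b[1] - a[1] == dc, name
        assert lm1.upper_margin_row - lm0.upper_margin_row == dr
        assert lm1.lower_margin_row - lm0.lower_margin_row == dr

    def test_recovery_within_2px_on_100_seeded_eyes(self):
        """Extracted landmarks track the generator's analytic coordinates."""
        rng = np.random.default_rng(99)
        worst = 0.0
        for i in range(100):
            geom, path = syn.sample_eye_params(rng, {"upper_retraction": 0.3},
                                               (512, 512), 0.1)
            _, mask, truth = syn.generate_eye(geom, path, seed=1000 + i)
            lm = geo.extract_landmarks(mask, geom.eye_side)
            t = truth.true_landmarks
            pairs = [
                (lm.pupil_center, t["pupil_center"]),
                (lm.medial_canthus, t["medial_canthus"]),
                (lm.lateral_canthus, t["lateral_canthus"]),
                (lm.punctum_ref, t["punctum_ref"]),
                (lm.iris_top, t["iris_top"]),
                (lm.iris_bottom, t["iris_bottom"]),
            ]
            for got, want in pairs:
                for g, w in zip(got, want):
                    worst = max(worst, abs(g - w))
            worst = max(worst, abs(lm.upper_margin_row - t["upper_margin_row"]))
            worst = max(worst, abs(lm.lower_margin_row - t["lower_margin_row"]))
        assert worst <= 2.0, f"worst landmark error {worst} px"


class TestCropStructures:
    def test_three_crops_emitted(self, healthy_eye, calib):
        img, mask, _ = healthy_eye
        crops = geo.crop_structures(img, mask, calib, out_size=64)
        assert set(crops) == {"eyelid", "conjunctiva", "lcp"}
        for c in crops.values():
            assert c.shape == (64, 64, 3)

    def test_conjunctiva_crop_sees_inflamed_texture(self, geom):
        healthy = syn.generate_eye(geom, PathologyParams(), seed=21)
        inflamed = syn.generate_eye(
            geom, PathologyParams(redness_conj=1.0), seed=21
        )
        ch = geo.crop_structures(healthy[0], healthy[1], out_size=64)
        ci = geo.crop_structures(inflamed[0], inflamed[1], out_size=64)
        # red shift: green channel drops markedly in the conjunctiva crop
        g_h = ch["conjunctiva"][..., 1].mean()
        g_i = ci["conjunctiva"][..., 1].mean()
        assert g_h - g_i > 10

    def test_lcp_crop_contains_lcp_pixels(self, healthy_eye, calib):
        img, mask, _ = healthy_eye
        # bounding box property: the unresized box holds >= 90% of the class
        grid = mask.grid
        region = grid == 4
        rows = np.nonzero(region.any(axis=1))[0]
        cols = np.nonzero(region.any(axis=0))[0]
        inside = region[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].sum()
        assert inside / region.sum() >= 0.9

    def test_empty_region_raises(self, healthy_eye, calib):
        img, mask, _ = healthy_eye
        grid = mask.grid.copy()
        grid[grid == 4] = 1
        with pytest.raises(MissingStructureError):
            geo.crop_structures(img, LabelMask(grid, "primary5"), calib)
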