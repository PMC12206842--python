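"""Generator contracts: determinism, mask/truth consistency, gaze-series
construction, face composition, cohort manifests and augmentation."""

import dataclasses

import numpy as np
import pytest

from tedeye import io as tio
from tedeye import synthetic as syn
from tedeye.errors import CalibrationError, DegenerateApertureError
from tedeye.types import (
    GAZE_FRAMES,
    EyeGeometryParams,
    PathologyParams,
    default_geometry,
)


class TestGenerateEye:
    def test_identical_seed_is_bit_identical(self, geom):
        path = PathologyParams(upper_retraction_mm=1.0, redness_conj=0.7)
        a = syn.generate_eye(geom, path, seed=3)
        b = syn.generate_eye(geom, path, seed=3)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1].grid, b[1].grid)
        assert a[2] == b[2]

    def test_healthy_truth_is_normal(self, healthy_eye):
        truth = healthy_eye[2]
        assert truth.true_retraction_category == "normal"
        assert truth.true_upper_show_mm == 0.0
        assert truth.true_lower_show_mm == 0.0
        assert all(v <= 0 for v in truth.true_overlap.values())

    def test_primary_mask_has_five_classes(self, healthy_eye):
        assert set(np.unique(healthy_eye[1].grid)) == {0, 1, 2, 3, 4}

    def test_retraction_band_pixel_count(self, geom):
        """2 mm of upper scleral show at 0.1 mm/px spans 20 +- 1 rows of
        sclera above the iris at the pupil column."""
        path = PathologyParams(upper_retraction_mm=2.0)
        _, mask, _ = syn.generate_eye(geom, path, seed=9)
        col = int(geom.pupil_center[1])
        colv = mask.grid[:, col]
        iris_rows = np.nonzero((colv == 2) | (colv == 3))[0]
        above = np.nonzero((colv == 1) & (np.arange(len(colv)) < iris_rows[0]))[0]
        assert len(above) == pytest.approx(20, abs=1)

    def test_mask_truth_consistency_by_pixel_counting(self, geom):
        """Recomputing D_up/D_down from the emitted mask matches the
        analytic truth within one pixel."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            path = PathologyParams(
                upper_retraction_mm=float(rng.uniform(0, 2.5)),
                lower_retraction_mm=float(rng.uniform(0, 2.5)),
            )
            _, mask, truth = syn.generate_eye(geom, path, seed=seed)
            col = int(geom.pupil_center[1])
            rows = np.nonzero(mask.grid[:, col] > 0)[0]
            d_up_px = geom.pupil_center[0] - rows[0]
            d_dn_px = rows[-1] - geom.pupil_center[0]
            assert d_up_px * geom.mm_per_px == pytest.approx(
                truth.true_D_up, abs=geom.mm_per_px
            )
            assert d_dn_px * geom.mm_per_px == pytest.approx(
                truth.true_D_down, abs=geom.mm_per_px
            )

    def test_degenerate_aperture_rejected(self, geom):
        bad = dataclasses.replace(geom, upper_lid_apex=-50.0, lower_lid_apex=40.0)
        with pytest.raises(DegenerateApertureError):
            syn.generate_eye(bad, PathologyParams(), seed=0)

    def test_invalid_pathology_rejected(self, geom):
        with pytest.raises(ValueError):
            syn.generate_eye(
                geom, PathologyParams(upper_retraction_mm=-1.0), seed=0
            )


class TestGazeSeries:
    def test_no_deficit_measures_below_thresholds(self, geom):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=2)
        truth = series["primary"][2]
        for d, m in truth.true_overlap.items():
            assert not syn.measure_is_disorder(d, m)

    def test_deficit_equals_truth_overlap(self, geom):
        series = syn.generate_gaze_series(
            geom, PathologyParams(gaze_limit={"up": 30.0}), seed=2
        )
        assert series["primary"][2].true_overlap["up"] == pytest.approx(30.0)
        assert series["primary"][2].true_disorder["up"]

    def test_gaze_masks_have_four_classes(self, geom):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=2)
        for frame in GAZE_FRAMES:
            assert set(np.unique(series[frame][1].grid)) <= {0, 1, 2, 3}
            assert set(np.unique(series[frame][1].grid)) >= {0, 1, 2}

    def test_head_fixed_aperture_identical_across_frames(self, geom):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=2)
        ref = series["primary"][1].grid > 0
        for frame in GAZE_FRAMES:
            assert np.array_equal(series[frame][1].grid > 0, ref)


class TestFaceCanvas:
    def test_division_length_and_mask_regions(self):
        gl = default_geometry(eye_side="left")
        gr = default_geometry(eye_side="right")
        img, mask = syn.generate_face(gl, gr, seed=4)
        # each rendered division spans 5 mm / (0.1 mm/px) = 50 px
        strip = mask.grid == 3
        rows, cols = np.nonzero(strip)
        c0 = cols.min()
        col = img[:, c0 + 2, 0].astype(float)
        binary = col > 127
        runs = np.diff(np.nonzero(np.diff(binary.astype(int)))[0])
        assert np.median(runs) == pytest.approx(50, abs=1)
        # regions disjoint and nonempty
        for cls in (1, 2, 3):
            assert (mask.grid == cls).any()

    def test_crop_recovers_eye_tile(self):
        from tedeye.geometry import locate_and_crop

        gl = default_geometry(eye_side="left")
        gr = default_geometry(eye_side="right")
        img, mask = syn.generate_face(gl, gr, seed=4)
        crops = locate_and_crop(img, mask)
        tile_r, _, _ = syn.generate_eye(
            gr, PathologyParams(), syn.derive_seed(4, 0)
        )
        assert np.array_equal(crops["right"][0], tile_r)

    def test_too_coarse_scale_rejected(self):
        gl = default_geometry(mm_per_px=2.0)
        gr = default_geometry(mm_per_px=2.0)
        with pytest.raises(CalibrationError):
            syn.generate_face(gl, gr, seed=0)


class TestCohort:
    def test_all_zero_prevalence_yields_normals(self, tmp_path):
        prev = {k: 0.0 for k in syn.DEFAULT_PREVALENCE}
        man = syn.generate_cohort(10, prev, seed=5, out_dir=tmp_path,
                                  image_size=(128, 128), mm_per_px=0.25)
        assert len(man) == 10
        assert (man.retraction_category == "normal").all()
        assert man.motility_disorder.sum() == 0

    def test_prevalence_within_binomial_error(self, tmp_path):
        man = syn.generate_cohort(272, {"upper_retraction": 0.42}, seed=6,
                                  out_dir=tmp_path, image_size=(128, 128),
                                  mm_per_px=0.25)
        k = (man.upper_retraction_mm > 0).sum()
        # 3 sigma of Binomial(272, 0.42)
        assert abs(k - 0.42 * 272) < 3 * np.sqrt(272 * 0.42 * 0.58)

    def test_split_ratio_8_1_1(self, tmp_path):
        man = syn.generate_cohort(20, {k: 0.0 for k in syn.DEFAULT_PREVALENCE},
                                  seed=7, out_dir=tmp_path,
                                  image_size=(128, 128), mm_per_px=0.25)
        assert (man.split == "train").sum() == 16
        assert (man.split == "val").sum() == 2
        assert (man.split == "test").sum() == 2

    def test_rerun_reproduces_manifest_bytes(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        syn.generate_cohort(6, None, seed=8, out_dir=a_dir,
                            image_size=(128, 128), mm_per_px=0.25)
        syn.generate_cohort(6, None, seed=8, out_dir=b_dir,
                            image_size=(128, 128), mm_per_px=0.25)
        assert (a_dir / "manifest.csv").read_bytes() == (
            b_dir / "manifest.csv").read_bytes()
        for p in sorted((a_dir / "masks").glob("*.png")):
            assert p.read_bytes() == (b_dir / "masks" / p.name).read_bytes()


class TestAugmentation:
    def test_flip_is_involution(self, healthy_eye):
        img, mask, _ = healthy_eye
        pairs = syn.augment_sample(img, mask, seed=1)
        flipped_img, flipped_mask = pairs[0]
        assert np.array_equal(flipped_img[:, ::-1], img)
        assert np.array_equal(flipped_mask.grid[:, ::-1], mask.grid)

    def test_brightness_factor_on_uniform_gray(self, healthy_eye):
        gray = np.full((32, 32, 3), 100, dtype=np.uint8)
        mask = dataclasses.replace(healthy_eye[1])
        mask = type(mask)(grid=np.zeros((32, 32), dtype=np.uint8),
                          ontology=mask.ontology)
        pairs = syn.augment_sample(gray, mask, seed=1)
        bright = pairs[1][0]
        assert np.all(bright == 150)

    def test_mask_classes_never_grow(self, healthy_eye):
        img, mask, _ = healthy_eye
        before = set(np.unique(mask.grid))
        for _, m in syn.augment_sample(img, mask, seed=3):
            assert set(np.unique(m.grid)) <= before

    def test_rotation_preserves_class_areas_within_5pct(self, healthy_eye):
        img, mask, _ = healthy_eye
        # seed chosen so the probabilistic rotation fires
        for seed in range(10):
            pairs = syn.augment_sample(img, mask, seed=seed)
            if len(pairs) == 6:
                rot_mask = pairs[5][1]
                for cls in (1, 2, 3, 4):
                    a = (mask.grid == cls).sum()
                    b = (rot_mask.grid == cls).sum()
                    assert abs(a - b) / a < 0.05
                return
        pytest.fail("rotation never applied in 10 seeds")

    def test_size_mismatch_raises(self, healthy_eye):
        img, mask, _ = healthy_eye
        with pytest.raises(ValueError):
            syn.augment_sample(img[:100], mask, seed=0)


def test_labelme_roundtrip(tmp_path):
    """A polygon annotation of the synthetic shapes rasterizes to the
    declared classes."""
    ann = {
        "imageHeight": 64,
        "imageWidth": 64,
        "shapes": [
            {"label": "sclera", "shape_type": "polygon",
             "points": [[10, 10], [54, 10], [54, 54], [10, 54]]},
            {"label": "iris", "shape_type": "polygon",
             "points": [[24, 24], [40, 24], [40, 40], [24, 40]]},
            {"label": "pupil", "shape_type": "polygon",
             "points": [[29, 29], [35, 29], [35, 35], [29, 35]]},
        ],
    }
    mask = tio.rasterize_labelme(ann, "gaze4")
    assert mask.grid[32, 32] == 3   # pupil wins inside iris
    assert mask.grid[26, 26] == 2
    assert mask.grid[12, 12] == 1
    assert mask.grid[0, 0] == 0
    with pytest.raises(ValueError):
        tio.rasterize_labelme(
            {"imageHeight": 8, "imageWidth": 8,
             "shapes": [{"label": "nonsense", "points": [[0, 0], [1, 0], [1, 1]]}]},
            "gaze4",
        )
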