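"""Quantitative rule logic: threshold boundaries, unit bookkeeping,
monotonicity and parameter recovery against generator truth."""

import dataclasses

import numpy as np
import pytest

from tedeye import diagnosis as dx
from tedeye import geometry as geo
from tedeye import synthetic as syn
from tedeye.errors import TedEyeError
from tedeye.types import (
    Calibration,
    GAZE_FRAMES,
    PathologyParams,
    default_geometry,
    resolve_direction,
)


def oracle_retraction(geom, path, seed, calib):
    _, mask, truth = syn.generate_eye(geom, path, seed)
    lm = geo.extract_landmarks(mask, geom.eye_side)
    return dx.diagnose_retraction(mask, lm, calib), truth


class TestRetractionRules:
    def test_healthy_eye_is_normal(self, geom, calib):
        res, _ = oracle_retraction(geom, PathologyParams(), 31, calib)
        assert res.category == "normal"
        assert res.upper_show_mm == 0.0 and res.lower_show_mm == 0.0
        assert not res.upper_flag and not res.lower_flag

    def test_upper_retraction_recovered(self, geom, calib):
        res, truth = oracle_retraction(
            geom, PathologyParams(upper_retraction_mm=2.0), 31, calib
        )
        assert res.category == "upper_only"
        assert res.upper_show_mm == pytest.approx(2.0, abs=2 * 0.1)
        assert res.upper_flag and not res.lower_flag

    def test_both_category(self, geom, calib):
        res, _ = oracle_retraction(
            geom,
            PathologyParams(upper_retraction_mm=1.0, lower_retraction_mm=1.0),
            31, calib,
        )
        assert res.category == "both"
        assert res.upper_flag and res.lower_flag

    def test_margin_diff_at_0p9_mm_flags_upper(self, geom, calib):
        """Rule: lower-minus-upper margin difference must exceed 1 mm; at
        0.9 mm with the cornea well exposed the upper flag fires even
        without scleral show."""
        tight = dataclasses.replace(
            geom,
            upper_lid_apex=47.0,   # D_up 4.7 mm (covers limbus: < 58 px)
            lower_lid_apex=56.0,   # D_down 5.6 mm -> margin diff 0.9 mm
        )
        _, mask, _ = syn.generate_eye(tight, PathologyParams(), seed=5)
        lm = geo.extract_landmarks(mask, tight.eye_side)
        res = dx.diagnose_retraction(mask, lm, calib)
        assert res.upper_show_mm == 0.0
        assert res.margin_diff_mm == pytest.approx(0.9, abs=0.15)
        assert res.upper_flag
        assert res.category == "normal"  # categorical levels use scleral show

    def test_missing_calibration_raises(self, healthy_eye):
        lm = geo.extract_landmarks(healthy_eye[1], "left")
        with pytest.raises(TedEyeError):
            dx.diagnose_retraction(healthy_eye[1], lm, None)

    def test_units_exact(self, geom):
        for mmpp in (0.05, 0.1, 0.2):
            calib = Calibration.from_mm_per_px(mmpp)
            g = default_geometry(mm_per_px=mmpp)
            res, _ = oracle_retraction(
                g, PathologyParams(upper_retraction_mm=1.5), 7, calib
            )
            # mm quantities are exactly px * mm_per_px
            assert res.D_up / calib.mm_per_px == pytest.approx(
                round(res.D_up / calib.mm_per_px), abs=1e-6
            )


class TestGazeRules:
    @pytest.mark.parametrize("overlap,expect", [(19.0, False), (20.0, True),
                                                (25.0, True)])
    def test_vertical_boundary_at_20px(self, geom, calib, overlap, expect):
        path = PathologyParams(gaze_limit={"up": overlap})
        series = syn.generate_gaze_series(geom, path, seed=17)
        mask = series["up"][1]
        lm = geo.extract_landmarks(mask, geom.eye_side)
        res = dx.diagnose_gaze("up", geom.eye_side, mask, lm, None, calib)
        assert res.disorder is expect
        assert res.measure_px == pytest.approx(overlap, abs=2)

    def test_lateral_zero_gap_is_normal(self, geom, calib):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=18)
        frame = "left" if resolve_direction(geom.eye_side, "left") == "lateral" \
            else "right"
        mask = series[frame][1]
        lm = geo.extract_landmarks(mask, geom.eye_side)
        res = dx.diagnose_gaze("lateral", geom.eye_side, mask, lm, None, calib)
        assert res.measure_px == 0.0
        assert not res.disorder

    def test_deficit_recovered_with_disorder(self, geom, calib):
        path = PathologyParams(gaze_limit={"up": 30.0})
        series = syn.generate_gaze_series(geom, path, seed=19)
        mask = series["up"][1]
        lm = geo.extract_landmarks(mask, geom.eye_side)
        res = dx.diagnose_gaze("up", geom.eye_side, mask, lm, None, calib)
        assert res.measure_px == pytest.approx(30, abs=2)
        assert res.disorder

    def test_medial_requires_primary_landmarks(self, geom, calib):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=20)
        frame = "left" if resolve_direction(geom.eye_side, "left") == "medial" \
            else "right"
        mask = series[frame][1]
        lm = geo.extract_landmarks(mask, geom.eye_side)
        with pytest.raises(TedEyeError):
            dx.diagnose_gaze("medial", geom.eye_side, mask, lm, None, calib)

    def test_unknown_direction_raises(self, geom, calib, healthy_eye):
        lm = geo.extract_landmarks(healthy_eye[1], geom.eye_side)
        with pytest.raises(TedEyeError):
            dx.diagnose_gaze("sideways", geom.eye_side, healthy_eye[1], lm,
                             None, calib)

    def test_measure_mm_is_px_times_calibration(self, geom, calib):
        path = PathologyParams(gaze_limit={"up": 26.0})
        series = syn.generate_gaze_series(geom, path, seed=21)
        mask = series["up"][1]
        lm = geo.extract_landmarks(mask, geom.eye_side)
        res = dx.diagnose_gaze("up", geom.eye_side, mask, lm, None, calib)
        assert res.measure_mm == pytest.approx(
            res.measure_px * calib.mm_per_px, abs=1e-12
        )


class TestMonotonicity:
    def test_increasing_deficit_never_unflags(self, geom, calib):
        """Once a synthetic deficit crosses its threshold, growing it
        further can only keep the disorder call positive."""
        last = False
        for overlap in (0.0, 10.0, 20.0, 30.0, 40.0):
            path = PathologyParams(gaze_limit={"up": overlap})
            series = syn.generate_gaze_series(geom, path, seed=23)
            mask = series["up"][1]
            lm = geo.extract_landmarks(mask, geom.eye_side)
            res = dx.diagnose_gaze("up", geom.eye_side, mask, lm, None, calib)
            assert not (last and not res.disorder)
            last = res.disorder
        assert last

    def test_increasing_retraction_never_unflags(self, geom, calib):
        last = False
        for ret in (0.0, 0.5, 1.0, 2.0, 3.0):
            res, _ = oracle_retraction(
                geom, PathologyParams(upper_retraction_mm=ret), 23, calib
            )
            assert not (last and not res.upper_flag)
            last = res.upper_flag
        assert last


class TestEyeReport:
    def test_healthy_series_all_normal(self, geom, calib):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=25)
        rep = dx.compile_eye_report(
            "e0", geom.eye_side, series["primary"][1],
            {f: series[f][1] for f in GAZE_FRAMES}, calib,
        )
        assert not rep.retraction.upper_flag
        assert not rep.retraction.lower_flag
        assert len(rep.motility) == 4
        assert not any(m.disorder for m in rep.motility)

    def test_single_medial_deficit_yields_one_disorder(self, geom, calib):
        deficit = syn.deficit_for_measure(geom, "medial", 8.0)
        path = PathologyParams(gaze_limit={"medial": deficit})
        series = syn.generate_gaze_series(geom, path, seed=26)
        rep = dx.compile_eye_report(
            "e1", geom.eye_side, series["primary"][1],
            {f: series[f][1] for f in GAZE_FRAMES}, calib,
        )
        calls = [m for m in rep.motility if m.disorder]
        assert len(calls) == 1 and calls[0].direction == "medial"

    def test_missing_gaze_frames_yield_absent_entries(self, geom, calib):
        series = syn.generate_gaze_series(geom, PathologyParams(), seed=27)
        rep = dx.compile_eye_report(
            "e2", geom.eye_side, series["primary"][1],
            {"up": series["up"][1]}, calib,
        )
        assert len(rep.motility) == 1

    def test_report_json_roundtrip(self, geom, calib):
        import json

        from tedeye.types import EyeReport

        series = syn.generate_gaze_series(
            geom, PathologyParams(gaze_limit={"up": 30.0}), seed=28
        )
        rep = dx.compile_eye_report(
            "e3", geom.eye_side, series["primary"][1],
            {f: series[f][1] for f in GAZE_FRAMES}, calib,
        )
        round_tripped = EyeReport.from_dict(
            json.loads(json.dumps(rep.to_dict()))
        )
        assert round_tripped == rep


class TestParameterRecovery:
    def test_upper_show_rmse_within_rasterization_bound(self):
        """Across 100 seeded eyes with retraction in [0, 3] mm, recovered
        upper show tracks truth within the ~2 px rasterization bound."""
        from tedeye.experiments import show_recovery_experiment

        out = show_recovery_experiment(seed=4242, which="upper")
        assert out["value"] <= 2 * 0.1

    def test_classification_exactness_on_margined_cohort(self):
        from tedeye.experiments import retraction_accuracy_experiment

        out = retraction_accuracy_experiment(seed=4242, n=60)
        assert out["value"] == 100.0
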