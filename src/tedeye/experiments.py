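"""Reproducible benchmark experiments on synthetic cohorts.

Each experiment regenerates its cohort from a seed, runs the relevant part
of the pipeline, and returns the headline number together with the problem
size.  They are the programmatic core of ``scripts/acceptance.py`` and of
the corresponding tests.

Problem sizes follow the package's desk-scale protocol: segmentation trains
a width-reduced network on a 200-eye cohort rendered at 128x128
(0.25 mm/px), and the rule-based diagnoses run on 100-eye cohorts rendered
at the full 512x512 working resolution (0.1 mm/px).
"""

from __future__ import annotations

import numpy as np

from . import synthetic as syn
from .diagnosis import compile_eye_report, diagnose_retraction
from .geometry import extract_landmarks
from .metrics import mean_pixel_accuracy, regression_metrics
from .synthetic import (
    MEASURE_THRESHOLDS,
    deficit_for_measure,
    derive_seed,
    generate_eye,
    generate_gaze_series,
    sample_cohort,
    sample_eye_params,
)
from .types import (
    ANATOMICAL_DIRECTIONS,
    Calibration,
    GAZE_FRAMES,
    PathologyParams,
)


# --------------------------------------------------------------------------
# Segmentation benchmark
# --------------------------------------------------------------------------

def segmentation_benchmark(seed: int, n: int = 200, image_size=(128, 128),
                           mm_per_px: float = 0.25, epochs: int = 30,
                           verbose: bool = False) -> dict:
    """Train the width-reduced segmentation net on a synthetic cohort and
    report mean pixel accuracy (percent) on the held-out test split."""
    from .nn.segnet import slim_config
    from .nn.train import TrainConfig, train_segmenter

    cohort = sample_cohort(n, None, seed, image_size, mm_per_px)
    arrays = {"train": [], "val": [], "test": []}
    for i, (geom, path, split) in enumerate(cohort):
        img, mask, _ = generate_eye(geom, path, derive_seed(seed, i, 1))
        arrays[split].append((img, mask.grid))

    def stack(split):
        imgs, masks = zip(*arrays[split])
        return np.stack(imgs), np.stack(masks)

    x_tr, y_tr = stack("train")
    x_va, y_va = stack("val")
    x_te, y_te = stack("test")

    model, history = train_segmenter(
        x_tr, y_tr, x_va, y_va,
        slim_config(5, image_size),
        TrainConfig(epochs=epochs, seed=derive_seed(seed, 555)),
        verbose=verbose,
    )
    pred = model.predict(x_te)
    mpa = mean_pixel_accuracy(pred, y_te, 5)
    return {
        "value": 100.0 * mpa,
        "n": n,
        "n_test": len(x_te),
        "best_val_mpa": float(history.val_mpa.max()),
        "history": history,
        "model": model,
    }


# --------------------------------------------------------------------------
# Rule-based diagnosis benchmarks (oracle masks)
# --------------------------------------------------------------------------

def _margined_eye(rng, mm_per_px=0.1, image_size=(512, 512)):
    geom, _ = sample_eye_params(rng, {}, image_size, mm_per_px)
    return geom


def retraction_accuracy_experiment(seed: int, n: int = 100) -> dict:
    """Accuracy (percent) of the upper-retraction call on a 50/50 cohort.

    Half the eyes carry an upper retraction of at least 0.3 mm; the other
    half are healthy draws.  Ground-truth masks feed the landmark and rule
    stages directly, isolating the analytic rules from model error.
    """
    rng = np.random.default_rng(derive_seed(seed, 801))
    calib = Calibration.from_mm_per_px(0.1)
    correct = 0
    for i in range(n):
        geom = _margined_eye(rng)
        diseased = i % 2 == 0
        path = PathologyParams(
            upper_retraction_mm=rng.uniform(0.3, 3.0) if diseased else 0.0
        )
        _, mask, truth = generate_eye(geom, path, derive_seed(seed, 802, i))
        lm = extract_landmarks(mask, geom.eye_side)
        result = diagnose_retraction(mask, lm, calib)
        if result.upper_flag == diseased:
            correct += 1
    return {"value": 100.0 * correct / n, "n": n}


def motility_accuracy_experiment(seed: int, n: int = 100) -> dict:
    """Per-direction accuracy (percent) of the motility calls on a gaze
    cohort; half the series have one direction's measure at least 5 px past
    its disorder threshold."""
    rng = np.random.default_rng(derive_seed(seed, 811))
    calib = Calibration.from_mm_per_px(0.1)
    correct = total = 0
    for i in range(n):
        geom = _margined_eye(rng)
        path = PathologyParams()
        if i % 2 == 0:
            direction = ANATOMICAL_DIRECTIONS[int(rng.integers(4))]
            _, thr = MEASURE_THRESHOLDS[direction]
            margin = rng.uniform(5.0, 30.0)
            path.gaze_limit = {
                direction: deficit_for_measure(geom, direction, thr + margin)
            }
        series = generate_gaze_series(geom, path, derive_seed(seed, 812, i))
        _, mask_p, truth = series["primary"]
        report = compile_eye_report(
            f"eye{i}", geom.eye_side, mask_p,
            {f: series[f][1] for f in GAZE_FRAMES}, calib,
        )
        for m in report.motility:
            correct += m.disorder == truth.true_disorder[m.direction]
            total += 1
    return {"value": 100.0 * correct / total, "n": n, "n_calls": total}


def show_recovery_experiment(seed: int, which: str, n: int = 100) -> dict:
    """RMSE (mm) of recovered scleral-show distances against truth.

    ``which`` selects the upper or lower lid; the show is drawn uniformly
    in [0, 3] mm at 0.1 mm/px and recovered from ground-truth masks via the
    landmark and calibration stages.
    """
    if which not in ("upper", "lower"):
        raise ValueError("which must be 'upper' or 'lower'")
    rng = np.random.default_rng(derive_seed(seed, 821 if which == "upper" else 822))
    calib = Calibration.from_mm_per_px(0.1)
    estimates, truths = [], []
    for i in range(n):
        geom = _margined_eye(rng)
        show = rng.uniform(0.0, 3.0)
        path = PathologyParams(**{f"{which}_retraction_mm": show})
        _, mask, truth = generate_eye(geom, path, derive_seed(seed, 823, i))
        lm = extract_landmarks(mask, geom.eye_side)
        result = diagnose_retraction(mask, lm, calib)
        estimates.append(
            result.upper_show_mm if which == "upper" else result.lower_show_mm
        )
        truths.append(
            truth.true_upper_show_mm if which == "upper"
            else truth.true_lower_show_mm
        )
    reg = regression_metrics(estimates, truths)
    return {"value": reg["rmse"], "n": n, "mse": reg["mse"], "r2": reg["r2"]}


def run_all_targets(seed: int, verbose: bool = False) -> dict:
    """Recompute every benchmark quantity from scratch."""
    seg = segmentation_benchmark(seed, verbose=verbose)
    return {
        "t7": {"value": seg["value"], "n": seg["n"]},
        "t8": {k: v for k, v in retraction_accuracy_experiment(seed).items()
               if k in ("value", "n")},
        "t9": {k: v for k, v in motility_accuracy_experiment(seed).items()
               if k in ("value", "n")},
        "t10": {k: v for k, v in show_recovery_experiment(seed, "upper").items()
                if k in ("value", "n")},
        "t11": {k: v for k, v in show_recovery_experiment(seed, "lower").items()
                if k in ("value", "n")},
    }
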