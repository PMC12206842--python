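"""Segmentation, diagnostic and regression metrics, and dataset prevalence
summaries.

Per-class segmentation quality uses IoU = p_ii / (p_ii + p_ij + p_ji) and
Dice = 2 p_ii / (2 p_ii + p_ij + p_ji); MPA is the mean per-class pixel
accuracy over all K+1 classes including background.  Diagnostic calls are
scored with ACC, precision and TPR.  Metrics whose denominator is empty are
reported as ``None`` ("undefined"), never silently smoothed to 0 or 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import LabelMask


def _as_grid(mask) -> np.ndarray:
    return mask.grid if isinstance(mask, LabelMask) else np.asarray(mask)


def confusion_counts(pred, true, n_classes: int) -> np.ndarray:
    """(n_classes, n_classes) matrix with rows = true class, cols = predicted."""
    pred = _as_grid(pred).ravel()
    true = _as_grid(true).ravel()
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    idx = true.astype(np.int64) * n_classes + pred.astype(np.int64)
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def segmentation_metrics(pred, true, n_classes: int | None = None) -> dict:
    """Per-class IoU and Dice plus MPA for a predicted/true mask pair.

    Classes absent from both masks get ``None`` for every per-class metric
    and are excluded from the MPA average (their pixel accuracy is
    undefined, not 1).
    """
    pg, tg = _as_grid(pred), _as_grid(true)
    if pg.shape != tg.shape:
        raise ValueError(f"shape mismatch: pred {pg.shape} vs true {tg.shape}")
    if n_classes is None:
        n_classes = int(max(pg.max(), tg.max())) + 1
    cm = confusion_counts(pg, tg, n_classes)

    iou, dice, pa = {}, {}, {}
    for c in range(n_classes):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        denom = tp + fp + fn
        if denom == 0:
            iou[c] = dice[c] = pa[c] = None
            continue
        iou[c] = tp / denom
        dice[c] = 2 * tp / (2 * tp + fp + fn)
        pa[c] = tp / (tp + fn) if (tp + fn) > 0 else None

    defined = [v for v in pa.values() if v is not None]
    mpa = float(np.mean(defined)) if defined else None
    return {"iou": iou, "dice": dice, "pixel_accuracy": pa, "mpa": mpa}


def mean_pixel_accuracy(pred, true, n_classes: int | None = None) -> float:
    return segmentation_metrics(pred, true, n_classes)["mpa"]


def diagnostic_metrics(predicted, true) -> dict:
    """ACC, precision and TPR for aligned binary call vectors."""
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(true, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    total = tp + fp + fn + tn
    return {
        "acc": (tp + tn) / total if total else None,
        "precision": tp / (tp + fp) if (tp + fp) else None,
        "tpr": tp / (tp + fn) if (tp + fn) else None,
        "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def regression_metrics(estimates, truths) -> dict:
    """MSE, RMSE (= sqrt of MSE by construction) and R-squared."""
    e = np.asarray(estimates, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if e.shape != t.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {t.shape}")
    if e.size < 2:
        raise ValueError("need at least two paired values")
    if not (np.isfinite(e).all() and np.isfinite(t).all()):
        raise ValueError("estimates and truths must be finite")
    resid = e - t
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "r2": r2}


def prevalence_summary(counts: dict | pd.DataFrame, denominators: dict) -> dict:
    """Per-symptom percentages rounded to the nearest integer.

    ``counts`` maps symptom -> positive count, or is a manifest DataFrame
    whose 0/1 symptom columns are summed.  ``denominators`` maps symptom ->
    the eye count of its dataset.
    """
    if isinstance(counts, pd.DataFrame):
        counts = {
            k: int(counts[k].sum()) for k in denominators if k in counts.columns
        }
    out = {}
    for name, count in counts.items():
        denom = denominators.get(name)
        if denom is None:
            continue
        if denom <= 0:
            raise ValueError(f"denominator for {name!r} must be positive")
        out[name] = int(round(100.0 * count / denom))
    return out
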