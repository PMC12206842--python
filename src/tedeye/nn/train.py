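"""Seeded training loops for the segmentation and classification networks.

Training uses adaptive moment estimation (Adam) with an initial learning
rate of 5e-4 decayed on a cosine schedule, batch size 8, and a weighted
cross-entropy objective for segmentation (per-label binary cross-entropy
for classification).  Model selection keeps the parameters with the best
validation mean pixel accuracy (segmentation) or validation accuracy
(classification).  With a fixed seed and single-threaded execution the loop
is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..metrics import mean_pixel_accuracy
from . import autograd as ag
from .autograd import Tensor
from .clsnet import ClsNetConfig, TBRMNet
from .layers import Adam, cosine_lr
from .segnet import DSRNet, SegNetConfig, ClassWeights, PRIMARY_WEIGHTS, normalize_images


@dataclass
class TrainConfig:
    lr: float = 5e-4
    final_lr: float = 1e-5
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    #: On-the-fly geometric augmentation (random horizontal flip plus a
    #: probabilistic deflection in (-20, +20) degrees at probability 0.5);
    #: regularizes the small-structure classes against memorization.
    augment: bool = True


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _augment_batch(x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Random flip and rotation applied identically to images and masks."""
    from scipy import ndimage

    x = x.copy()
    y = y.copy()
    for i in range(len(x)):
        if rng.random() < 0.5:
            x[i] = x[i, :, :, ::-1]
            y[i] = y[i, :, ::-1]
        if rng.random() < 0.5:
            angle = rng.uniform(-20.0, 20.0)
            for c in range(x.shape[1]):
                x[i, c] = ndimage.rotate(
                    x[i, c], angle, reshape=False, order=1, mode="nearest"
                )
            y[i] = ndimage.rotate(
                y[i], angle, reshape=False, order=0, mode="constant"
            )
    return x, y


def train_segmenter(train_images: np.ndarray, train_masks: np.ndarray,
                    val_images: np.ndarray, val_masks: np.ndarray,
                    seg_config: SegNetConfig,
                    train_config: TrainConfig | None = None,
                    class_weights: ClassWeights | None = None,
                    verbose: bool = False):
    """Train DSR-Net on uint8 images and integer masks.

    Returns ``(model, history)`` where ``history`` is a DataFrame with one
    row per epoch (training loss, validation MPA, learning rate); the model
    carries the best-validation-MPA parameters.
    """
    tc = train_config or TrainConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ConfigurationError("empty training or validation split")
    weights = (class_weights or PRIMARY_WEIGHTS).full()
    if len(weights) != seg_config.n_classes:
        raise ConfigurationError(
            f"{seg_config.n_classes} classes need {seg_config.n_classes} "
            f"weights, got {len(weights)}"
        )

    model = DSRNet(seg_config, seed=tc.seed)
    opt = Adam(model.parameters(), lr=tc.lr)
    rng = np.random.default_rng(tc.seed)

    x_train = normalize_images(train_images)
    y_train = np.ascontiguousarray(train_masks, dtype=np.int64)

    best_mpa, best_state = -1.0, None
    rows = []
    for epoch in range(tc.epochs):
        opt.lr = cosine_lr(tc.lr, tc.final_lr, epoch, tc.epochs)
        model.set_training(True)
        losses = []
        for idx in _batches(len(x_train), tc.batch_size, rng):
            xb, yb = x_train[idx], y_train[idx]
            if tc.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            opt.zero_grad()
            loss = ag.weighted_softmax_cross_entropy(
                model(Tensor(xb)), yb, weights
            )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        pred = model.predict(val_images, batch_size=tc.batch_size)
        mpa = mean_pixel_accuracy(pred, val_masks, seg_config.n_classes)
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_mpa": mpa, "lr": opt.lr}
        )
        if verbose:
            print(f"epoch {epoch:3d} loss {rows[-1]['train_loss']:.4f} "
                  f"val MPA {mpa:.4f}")
        if mpa is not None and mpa > best_mpa:
            best_mpa = mpa
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}

    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, pd.DataFrame(rows)


def train_classifier(train_crops: np.ndarray, train_labels: np.ndarray,
                     val_crops: np.ndarray, val_labels: np.ndarray,
                     cls_config: ClsNetConfig,
                     train_config: TrainConfig | None = None,
                     verbose: bool = False):
    """Train one TBRM-Net head on uint8 crops and 0/1 label matrices.

    Label columns follow ``cls_config.labels``.  Model selection keeps the
    parameters with the best mean per-label validation accuracy at the 0.5
    decision threshold.
    """
    tc = train_config or TrainConfig()
    if len(train_crops) == 0 or len(val_crops) == 0:
        raise ConfigurationError("empty training or validation split")
    n_labels = len(cls_config.labels)
    if train_labels.shape[1] != n_labels:
        raise ConfigurationError(
            f"head {cls_config.structure!r} expects {n_labels} label "
            f"columns, got {train_labels.shape[1]}"
        )

    model = TBRMNet(cls_config, seed=tc.seed)
    opt = Adam(model.parameters(), lr=tc.lr)
    rng = np.random.default_rng(tc.seed)

    x_train = normalize_images(train_crops)
    y_train = np.asarray(train_labels, dtype=np.float64)

    best_acc, best_state = -1.0, None
    rows = []
    for epoch in range(tc.epochs):
        opt.lr = cosine_lr(tc.lr, tc.final_lr, epoch, tc.epochs)
        model.set_training(True)
        losses = []
        for idx in _batches(len(x_train), tc.batch_size, rng):
            opt.zero_grad()
            loss = ag.bce_with_logits(model(Tensor(x_train[idx])), y_train[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        probs = model.predict_proba(val_crops)
        acc = float(np.mean((probs >= 0.5) == (val_labels > 0.5)))
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_acc": acc, "lr": opt.lr}
        )
        if verbose:
            print(f"epoch {epoch:3d} loss {rows[-1]['train_loss']:.4f} "
                  f"val acc {acc:.4f}")
        if acc > best_acc:
            best_acc = acc
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}

    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, pd.DataFrame(rows)
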