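"""DSR-Net: U-shaped semantic segmentation with SE-recalibrated skips and a
dense-atrous + multi-kernel-pooling context bottleneck.

The encoder opens with a 7x7 stride-2 convolution and 2x2 max pooling, then
three residual stages (the last two strided), for four downsamplings in
total.  The bottleneck applies the DAC block then the RMP block.  The
decoder restores resolution with four stride-2 deconvolutions; at each of
the first three, the matching encoder feature map passes through a
squeeze-and-excitation block and is added to the upsampled features.  A 1x1
convolution produces per-pixel class logits at the input resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import ConfigurationError
from . import autograd as ag
from .autograd import Tensor
from .blocks import DACBlock, RMPBlock, ResidualBlock, SEBlock
from .layers import BatchNorm2d, Conv2d, ConvBNReLU, ConvTranspose2d, Module


@dataclass
class SegNetConfig:
    n_classes: int = 5
    widths: tuple = (64, 128, 256, 512)
    se_ratio: int = 16
    dac_dilations: tuple = (1, 3, 5)
    rmp_pool_sizes: tuple = (2, 3, 5, 6)
    input_size: tuple = (512, 512)

    def validate(self) -> None:
        if len(self.widths) != 4:
            raise ConfigurationError("widths must list four encoder stages")
        for w in self.widths[:3]:  # skip-connection widths pass through SE
            if w % self.se_ratio != 0:
                raise ConfigurationError(
                    f"SE ratio {self.se_ratio} must divide skip width {w}"
                )
        if any(s % 16 != 0 for s in self.input_size):
            raise ConfigurationError("input size must be divisible by 16")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SegNetConfig":
        d = json.loads(s)
        for k in ("widths", "dac_dilations", "rmp_pool_sizes", "input_size"):
            d[k] = tuple(d[k])
        return cls(**d)


def slim_config(n_classes: int = 5, input_size=(128, 128)) -> SegNetConfig:
    """Width-reduced configuration for CPU-scale experiments.

    Dilations and pooling scales shrink with the input so the bottleneck
    (input/16) still satisfies the context blocks' receptive-field and pool
    size requirements: the default (1, 3, 5) dilations assume the 32x32
    bottleneck of a 512x512 input.
    """
    bottleneck = min(input_size) // 16
    if bottleneck >= 11:
        dil, pools = (1, 3, 5), (2, 3, 5, 6)
    elif bottleneck >= 8:
        dil, pools = (1, 2, 3), (2, 3, 4, 6)
    elif bottleneck >= 4:
        dil, pools = (1, 1, 1), (1, 2, 3, 4)
    else:
        raise ConfigurationError(
            f"input {input_size} leaves a {bottleneck}-pixel bottleneck; "
            "use at least a 64-pixel input"
        )
    return SegNetConfig(
        n_classes=n_classes,
        widths=(12, 24, 48, 96),
        se_ratio=4,
        dac_dilations=dil,
        rmp_pool_sizes=pools,
        input_size=tuple(input_size),
    )


@dataclass
class ClassWeights:
    """Per-class loss weights; the background weight defaults to 1 and the
    foreground weights emphasize the small diagnostically-important
    structures."""

    foreground: tuple = (1.0, 4.0, 4.0, 8.0)  # sclera, iris, pupil, lcp
    background: float = 1.0

    def full(self) -> np.ndarray:
        w = np.array([self.background, *self.foreground], dtype=np.float64)
        if (w <= 0).any():
            raise ConfigurationError("class weights must be positive")
        return w


PRIMARY_WEIGHTS = ClassWeights(foreground=(1.0, 4.0, 4.0, 8.0))
GAZE_WEIGHTS = ClassWeights(foreground=(1.0, 4.0, 8.0))


class DSRNet(Module):
    def __init__(self, config: SegNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = config.widths

        self.stem_conv = Conv2d(3, w0, 7, rng, stride=2, pad=3)
        self.stem_bn = BatchNorm2d(w0)
        self.enc1 = ResidualBlock(w0, w1, rng, stride=1)
        self.enc2 = ResidualBlock(w1, w2, rng, stride=2)
        self.enc3 = ResidualBlock(w2, w3, rng, stride=2)

        self.dac = DACBlock(w3, rng, config.dac_dilations)
        self.rmp = RMPBlock(w3, rng, config.rmp_pool_sizes)

        self.se2 = SEBlock(w2, config.se_ratio, rng)
        self.se1 = SEBlock(w1, config.se_ratio, rng)
        self.se0 = SEBlock(w0, config.se_ratio, rng)

        cb = w3 + self.rmp.extra_channels
        self.up3 = ConvTranspose2d(cb, w2, rng)
        self.dec3 = ConvBNReLU(w2, w2, 3, rng)
        self.up2 = ConvTranspose2d(w2, w1, rng)
        self.dec2 = ConvBNReLU(w1, w1, 3, rng)
        self.up1 = ConvTranspose2d(w1, w0, rng)
        self.dec1 = ConvBNReLU(w0, w0, 3, rng)
        self.up0 = ConvTranspose2d(w0, w0, rng)
        self.dec0 = ConvBNReLU(w0, w0, 3, rng)
        self.head = Conv2d(w0, config.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2:] != tuple(self.config.input_size):
            raise ConfigurationError(
                f"input {x.shape[2:]} does not match configured size "
                f"{self.config.input_size}"
            )
        s0 = ag.relu(self.stem_bn(self.stem_conv(x)))   # /2, w0
        p = ag.maxpool2d(s0, 2)                          # /4
        s1 = self.enc1(p)                                # /4, w1
        s2 = self.enc2(s1)                               # /8, w2
        s3 = self.enc3(s2)                               # /16, w3

        b = self.rmp(self.dac(s3))                       # /16, w3 + 4

        d3 = self.dec3(ag.relu(ag.add(self.up3(b), self.se2(s2))))
        d2 = self.dec2(ag.relu(ag.add(self.up2(d3), self.se1(s1))))
        d1 = self.dec1(ag.relu(ag.add(self.up1(d2), self.se0(s0))))
        d0 = self.dec0(ag.relu(self.up0(d1)))
        return self.head(d0)

    # ---------------- inference helpers ----------------

    def scores(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel softmax class scores for a batch of uint8 RGB images."""
        self.set_training(False)
        x = Tensor(normalize_images(images))
        z = self.forward(x).data.astype(np.float64)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Argmax class masks for a batch of uint8 RGB images."""
        out = []
        for i in range(0, len(images), batch_size):
            out.append(self.scores(images[i:i + batch_size]).argmax(axis=1))
        return np.concatenate(out).astype(np.uint8)


def normalize_images(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) or (H, W, 3) -> float32 (N, 3, H, W) in ~[-2, 2]."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    arr = arr.transpose(0, 3, 1, 2)
    return (arr / 255.0 - 0.5) / 0.25


def segnet_forward(image: np.ndarray, config: SegNetConfig, seed: int = 0) -> np.ndarray:
    """One-shot forward pass: per-pixel softmax scores for a single image."""
    net = DSRNet(config, seed=seed)
    return net.scores(image)[0]


def save_checkpoint(path, model: DSRNet, seed: int) -> None:
    arrays = model.state_arrays()
    np.savez_compressed(
        path,
        __config__=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8),
        __seed__=np.asarray(seed),
        **arrays,
    )


def load_checkpoint(path) -> DSRNet:
    with np.load(path) as data:
        config = SegNetConfig.from_json(bytes(data["__config__"]).decode())
        seed = int(data["__seed__"])
        model = DSRNet(config, seed=seed)
        model.load_state_arrays(
            {k: data[k] for k in data.files if not k.startswith("__")}
        )
    return model
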