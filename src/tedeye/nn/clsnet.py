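"""TBRM-Net: dual-branch multi-label classifier of ocular inflammation.

The first branch extracts features through a strided stem with max pooling
and a residual block, then a MobileViT-style block integrates local and
global context.  The second branch stacks 3x3 convolution blocks; at each
stage its features are concatenated with the first branch's and fused by a
1x1 convolution.  The branch outputs are multiplied elementwise (so either
branch can gate the other), reduced by a 3x3 convolution, global-average
pooled, flattened, and mapped to one sigmoid output per inflammation label.
Each structure crop (eyelid, conjunctiva, caruncle-plica) has its own head:
"normal" is not a trained output but the decision-level complement of the
positive labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ..errors import ConfigurationError
from . import autograd as ag
from .autograd import Tensor
from .blocks import MobileViTBlock, ResidualBlock
from .layers import Conv2d, ConvBNReLU, Linear, Module

#: Trainable label sets per structure crop; "normal" is derived at decision
#: time as the absence of every positive label.
HEAD_SPECS = {
    "eyelid": ("redness_eyelid", "swelling_eyelid"),
    "conjunctiva": ("redness_conj", "swelling_conj"),
    "lcp": ("swelling_lcp",),
}

DECISION_THRESHOLD = 0.5


@dataclass
class ClsNetConfig:
    structure: str = "eyelid"
    widths: tuple = (8, 16)
    input_size: int = 64

    def validate(self) -> None:
        if self.structure not in HEAD_SPECS:
            raise ConfigurationError(
                f"unknown structure {self.structure!r}; expected one of "
                f"{sorted(HEAD_SPECS)}"
            )
        if self.input_size % 8 != 0:
            raise ConfigurationError("input size must be divisible by 8")

    @property
    def labels(self) -> tuple:
        return HEAD_SPECS[self.structure]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ClsNetConfig":
        d = json.loads(s)
        d["widths"] = tuple(d["widths"])
        return cls(**d)


@dataclass
class MultiLabelPrediction:
    structure: str
    probabilities: dict  # label -> p in [0, 1]
    decisions: dict      # label -> bool, plus "normal"

    @classmethod
    def from_probs(cls, structure: str, labels, probs) -> "MultiLabelPrediction":
        probabilities = {l: float(p) for l, p in zip(labels, probs)}
        decisions = {l: bool(p >= DECISION_THRESHOLD) for l, p in probabilities.items()}
        decisions["normal"] = not any(decisions.values())
        return cls(structure, probabilities, decisions)


class TBRMNet(Module):
    def __init__(self, config: ClsNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        w0, w1 = config.widths

        # branch 1: residual stem + MobileViT global stage
        self.b1_stem = ConvBNReLU(3, w0, 3, rng, stride=2)        # /2
        self.b1_res = ResidualBlock(w0, w1, rng, stride=2)        # /4 (after pool /8)
        self.b1_vit = MobileViTBlock(w1, rng)

        # branch 2: stacked 3x3 blocks with per-stage concat fusion
        self.b2_s1 = ConvBNReLU(3, w0, 3, rng, stride=2)          # /2
        self.fuse1 = Conv2d(2 * w0, w0, 1, rng)
        self.b2_s2 = ConvBNReLU(w0, w0, 3, rng, stride=2)         # /4
        self.fuse2 = Conv2d(2 * w0, w0, 1, rng)
        self.b2_s3 = ConvBNReLU(w0, w1, 3, rng, stride=2)         # /8
        self.fuse3 = Conv2d(2 * w1, w1, 1, rng)

        self.reduce = ConvBNReLU(w1, w0, 3, rng)
        self.fc = Linear(w0, len(config.labels), rng)

    def forward(self, x: Tensor, ablate_branch2: bool = False) -> Tensor:
        """Logits (N, n_labels).  ``ablate_branch2`` zeroes the second
        branch's final features to expose the multiplicative fusion."""
        b1_a = self.b1_stem(x)                    # /2, w0
        b1_b = ag.maxpool2d(b1_a, 2)              # /4, w0
        b1_c = self.b1_res(b1_b)                  # /8, w1
        b1 = self.b1_vit(b1_c)                    # /8, w1

        y = self.b2_s1(x)                         # /2, w0
        y = ag.relu(self.fuse1(ag.concat([y, b1_a], axis=1)))
        y = self.b2_s2(y)                         # /4, w0
        y = ag.relu(self.fuse2(ag.concat([y, b1_b], axis=1)))
        y = self.b2_s3(y)                         # /8, w1
        b2 = ag.relu(self.fuse3(ag.concat([y, b1_c], axis=1)))
        if ablate_branch2:
            b2 = ag.scale(b2, 0.0)

        fused = ag.mul(b1, b2)
        pooled = ag.global_avgpool(self.reduce(fused))
        return self.fc(pooled)

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a batch of uint8 crops."""
        from .segnet import normalize_images

        self.set_training(False)
        z = self.forward(Tensor(normalize_images(crops))).data.astype(np.float64)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, crops: np.ndarray) -> list[MultiLabelPrediction]:
        probs = self.predict_proba(crops)
        return [
            MultiLabelPrediction.from_probs(
                self.config.structure, self.config.labels, p
            )
            for p in probs
        ]


def tbrm_forward(crop: np.ndarray, config: ClsNetConfig,
                 seed: int = 0) -> MultiLabelPrediction:
    """One-shot forward pass for a single structure crop."""
    net = TBRMNet(config, seed=seed)
    return net.predict(crop[None])[0]


def classify_structures(crops: dict, heads: dict) -> dict:
    """Run each trained head on its structure crop.

    ``crops`` maps structure -> uint8 crop (missing structures allowed);
    ``heads`` maps structure -> trained :class:`TBRMNet`.  Missing crops are
    reported as unavailable rather than silently skipped.
    """
    out = {}
    for structure, net in heads.items():
        crop = crops.get(structure)
        if crop is None:
            out[structure] = None
            continue
        out[structure] = net.predict(crop[None])[0]
    return out
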