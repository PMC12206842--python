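"""Architecture blocks shared by the segmentation and classification nets.

* ``SEBlock`` — squeeze-and-excitation channel recalibration: global average
  pooling to a channel descriptor, a bottleneck FC pair (C -> C/r -> C) with
  ReLU then sigmoid, and per-channel rescaling of the input.
* ``DACBlock`` — dense atrous convolution: four cascaded branches of dilated
  3x3 convolutions with increasing receptive field, each closed by a 1x1
  convolution and ReLU, summed with the input.
* ``RMPBlock`` — residual multi-kernel pooling: max pooling at four scales,
  1x1 reduction to a single channel per scale, nearest upsampling back to
  the input size and concatenation with the input (channels C + 4).
* ``ResidualBlock`` — two 3x3 conv/BN pairs with an identity (or projected)
  shortcut.
* ``MobileViTBlock`` — local 3x3 convolution, pointwise projection to an
  embedding, a single-stage transformer over the spatial tokens for global
  context, pointwise projection back and a 3x3 fusion convolution over the
  concatenation with the input.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from . import autograd as ag
from .autograd import Tensor
from .layers import BatchNorm2d, Conv2d, ConvBNReLU, Linear, Module


class SEBlock(Module):
    def __init__(self, channels: int, ratio: int, rng):
        if channels % ratio != 0:
            raise ConfigurationError(
                f"SE ratio {ratio} must divide the channel width {channels}"
            )
        self.fc1 = Linear(channels, channels // ratio, rng)
        self.fc2 = Linear(channels // ratio, channels, rng)
        self.last_weights: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        z = ag.global_avgpool(x)                       # (N, C)
        s = ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))  # (N, C) in [0, 1]
        self.last_weights = s.data.copy()
        n, c = s.shape
        return ag.mul(x, ag.reshape(s, (n, c, 1, 1)))


class DACBlock(Module):
    """Cascaded dilated branches; branch k reuses the first k dilations."""

    def __init__(self, channels: int, rng, dilations=(1, 3, 5)):
        d0, d1, d2 = dilations
        self.dilations = tuple(dilations)
        self.b1_conv = Conv2d(channels, channels, 3, rng, dil=d0)
        self.b2_conv = Conv2d(channels, channels, 3, rng, dil=d1)
        self.b2_point = Conv2d(channels, channels, 1, rng)
        self.b3_conv1 = Conv2d(channels, channels, 3, rng, dil=d0)
        self.b3_conv2 = Conv2d(channels, channels, 3, rng, dil=d1)
        self.b3_point = Conv2d(channels, channels, 1, rng)
        self.b4_conv1 = Conv2d(channels, channels, 3, rng, dil=d0)
        self.b4_conv2 = Conv2d(channels, channels, 3, rng, dil=d1)
        self.b4_conv3 = Conv2d(channels, channels, 3, rng, dil=d2)
        self.b4_point = Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        rf = 2 * max(self.dilations) + 1
        if min(x.shape[2], x.shape[3]) < rf:
            raise ConfigurationError(
                f"input {x.shape[2]}x{x.shape[3]} is smaller than the largest "
                f"effective receptive field {rf}"
            )
        b1 = ag.relu(self.b1_conv(x))
        b2 = ag.relu(self.b2_point(self.b2_conv(x)))
        b3 = ag.relu(self.b3_point(self.b3_conv2(self.b3_conv1(x))))
        b4 = ag.relu(self.b4_point(self.b4_conv3(self.b4_conv2(self.b4_conv1(x)))))
        out = ag.add(x, ag.add(ag.add(b1, b2), ag.add(b3, b4)))
        return out


class RMPBlock(Module):
    def __init__(self, channels: int, rng, pool_sizes=(2, 3, 5, 6)):
        self.pool_sizes = tuple(pool_sizes)
        self.points = [Conv2d(channels, 1, 1, rng) for _ in pool_sizes]

    @property
    def extra_channels(self) -> int:
        return len(self.pool_sizes)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if max(self.pool_sizes) > min(h, w):
            raise ConfigurationError(
                f"pool size {max(self.pool_sizes)} exceeds feature map "
                f"{h}x{w}"
            )
        branches = [x]
        for k, point in zip(self.pool_sizes, self.points):
            y = ag.upsample_to(point(ag.maxpool2d(x, k)), (h, w))
            branches.append(y)
        return ag.concat(branches, axis=1)


class ResidualBlock(Module):
    def __init__(self, cin: int, cout: int, rng, stride: int = 1):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(ag.relu(self.bn1(self.conv1(x)))))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return ag.relu(ag.add(y, skip))


class TransformerStage(Module):
    """Single-head self-attention + MLP over (N, S, d) token sequences."""

    def __init__(self, d: int, rng, mlp_ratio: int = 2):
        self.d = d
        self.ln1_g = Tensor(np.ones(d, dtype=ag.DTYPE), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(d, dtype=ag.DTYPE), requires_grad=True)
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.proj = Linear(d, d, rng)
        self.ln2_g = Tensor(np.ones(d, dtype=ag.DTYPE), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(d, dtype=ag.DTYPE), requires_grad=True)
        self.mlp1 = Linear(d, mlp_ratio * d, rng)
        self.mlp2 = Linear(mlp_ratio * d, d, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        h = ag.layernorm_lastaxis(tokens, self.ln1_g, self.ln1_b)
        q, k, v = self.q(h), self.k(h), self.v(h)
        attn = ag.softmax_lastaxis(
            ag.scale(ag.matmul(q, transpose_last(k)), 1.0 / np.sqrt(self.d))
        )
        tokens = ag.add(tokens, self.proj(ag.matmul(attn, v)))
        h = ag.layernorm_lastaxis(tokens, self.ln2_g, self.ln2_b)
        return ag.add(tokens, self.mlp2(ag.relu(self.mlp1(h))))


def transpose_last(x: Tensor) -> Tensor:
    axes = list(range(len(x.shape)))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return ag.transpose(x, tuple(axes))


class MobileViTBlock(Module):
    def __init__(self, channels: int, rng, embed_dim: int | None = None):
        d = embed_dim or channels
        self.local = ConvBNReLU(channels, channels, 3, rng)
        self.to_embed = Conv2d(channels, d, 1, rng)
        self.transformer = TransformerStage(d, rng)
        self.from_embed = Conv2d(d, channels, 1, rng)
        self.fuse = ConvBNReLU(2 * channels, channels, 3, rng)
        self.d = d

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        y = self.to_embed(self.local(x))
        tokens = ag.transpose(ag.reshape(y, (n, self.d, h * w)), (0, 2, 1))
        tokens = self.transformer(tokens)
        y = ag.reshape(ag.transpose(tokens, (0, 2, 1)), (n, self.d, h, w))
        y = self.from_embed(y)
        return self.fuse(ag.concat([x, y], axis=1))
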