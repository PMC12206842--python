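"""Trainable layer modules over the autograd ops.

Modules hold :class:`~tedeye.nn.autograd.Tensor` parameters, recurse through
attributes for parameter collection, and carry a shared training-mode flag
(batch statistics vs running statistics in batch normalization).  Weight
initialization is He-normal and driven by an explicit
``numpy.random.Generator`` so that identically seeded models are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    training = True

    def parameters(self):
        seen = set()
        for obj in self.__dict__.values():
            if isinstance(obj, Tensor) and obj.requires_grad and id(obj) not in seen:
                seen.add(id(obj))
                yield obj
            elif isinstance(obj, Module):
                yield from obj.parameters()
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def modules(self):
        yield self
        for obj in self.__dict__.values():
            if isinstance(obj, Module):
                yield from obj.modules()
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict:
        """Flat name -> ndarray map of parameters and buffers."""
        out = {}

        def walk(mod, prefix):
            for name, obj in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(obj, Tensor) and obj.requires_grad:
                    out[key] = obj.data
                elif isinstance(obj, np.ndarray):
                    out[key] = obj
                elif isinstance(obj, Module):
                    walk(obj, key + ".")
                elif isinstance(obj, (list, tuple)):
                    for i, item in enumerate(obj):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict):
        own = self.state_arrays()
        missing = set(own) - set(arrays)
        if missing:
            raise KeyError(f"checkpoint is missing arrays: {sorted(missing)[:5]} ...")

        def walk(mod, prefix):
            for name, obj in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(obj, Tensor) and obj.requires_grad:
                    obj.data = np.asarray(arrays[key], dtype=obj.data.dtype)
                elif isinstance(obj, np.ndarray):
                    obj[...] = arrays[key]
                elif isinstance(obj, Module):
                    walk(obj, key + ".")
                elif isinstance(obj, (list, tuple)):
                    for i, item in enumerate(obj):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(ag.DTYPE)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=None, dil=1, bias=True):
        self.stride, self.dil = stride, dil
        self.pad = (dil * (k - 1)) // 2 if pad is None else pad
        self.w = Tensor(_he(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=ag.DTYPE), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.w, self.b, self.stride, self.pad, self.dil)


class ConvTranspose2d(Module):
    """Stride-2, kernel-4, pad-1 transposed convolution (doubles H and W)."""

    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1):
        self.stride, self.pad = stride, pad
        self.w = Tensor(_he(rng, (cin, cout, k, k), cin * k * k), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=ag.DTYPE), requires_grad=True)

    def forward(self, x):
        return ag.conv_transpose2d(x, self.w, self.b, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1):
        self.gamma = Tensor(np.ones(c, dtype=ag.DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=ag.DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum

    def forward(self, x):
        return ag.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum,
        )


class Linear(Module):
    def __init__(self, fin, fout, rng, bias=True):
        self.w = Tensor(_he(rng, (fin, fout), fin), requires_grad=True)
        self.b = Tensor(np.zeros(fout, dtype=ag.DTYPE), requires_grad=True) if bias else None

    def forward(self, x):
        y = ag.matmul(x, self.w)
        return ag.add(y, self.b) if self.b is not None else y


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k, rng, stride=1, dil=1):
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, dil=dil)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class Adam:
    """Adaptive moment estimation with optional cosine learning-rate decay."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(initial: float, final: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay of the learning rate from ``initial`` to ``final``."""
    if total_epochs <= 1:
        return initial
    frac = epoch / (total_epochs - 1)
    return final + 0.5 * (initial - final) * (1 + np.cos(np.pi * frac))
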