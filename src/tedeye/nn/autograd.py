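"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the segmentation and classification
networks: a :class:`Tensor` wrapping a float32 ndarray, a small set of
differentiable operations (convolution, transposed convolution, pooling,
normalization, matrix products, activations, losses) with hand-written
backward passes, and topological-order backpropagation.  Convolutions are
im2col + GEMM; the transposed convolution reuses the convolution's
input-gradient kernel, so one set of three conv kernels serves both layer
types.  All backward passes are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.parents = parents
        self.grad_fn = grad_fn  # grad_out -> tuple of parent grads (or None)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t.grad_fn is None:
                continue
            gs = t.grad_fn(t.grad)
            for p, g in zip(t.parents, gs):
                if g is None or not p.requires_grad:
                    continue
                g = g.astype(DTYPE, copy=False)
                p.grad = g if p.grad is None else p.grad + g
            # free intermediate gradients early
            if t is not self:
                t.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# --------------------------------------------------------------------------
# Elementwise and shape ops
# --------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum a gradient over the axes that were broadcast in the forward op."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))
    out.grad_fn = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))
    out.grad_fn = lambda g: (
        _unbroadcast(g * b.data, a.shape),
        _unbroadcast(g * a.data, b.shape),
    )
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, parents=(a,))
    out.grad_fn = lambda g: (g * s,)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out.grad_fn = lambda g: (g * mask,)
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    y = y.astype(DTYPE)
    out = Tensor(y, parents=(x,))
    out.grad_fn = lambda g: (g * y * (1.0 - y),)
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))
    out.grad_fn = lambda g: (g.reshape(x.shape),)
    return out


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(x.data.transpose(axes), parents=(x,))
    out.grad_fn = lambda g: (g.transpose(inv),)
    return out


def concat(tensors, axis=1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    out.grad_fn = grad_fn
    return out


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size
    out = Tensor(np.asarray(x.data.mean()), parents=(x,))
    out.grad_fn = lambda g: (np.broadcast_to(g / n, x.shape).astype(DTYPE),)
    return out


# --------------------------------------------------------------------------
# Dense algebra
# --------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product (numpy broadcasting rules, >= 2-D operands)."""
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def grad_fn(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    out.grad_fn = grad_fn
    return out


def softmax_lastaxis(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = (e / e.sum(axis=-1, keepdims=True)).astype(DTYPE)
    out = Tensor(y, parents=(x,))

    def grad_fn(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        return (y * (g - dot),)

    out.grad_fn = grad_fn
    return out


def layernorm_lastaxis(x: Tensor, gamma: Tensor, beta: Tensor, eps=1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    d = x.shape[-1]

    def grad_fn(g):
        gxhat = g * gamma.data
        gx = inv * (
            gxhat
            - gxhat.mean(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(g.ndim - 1))
        return gx, (g * xhat).sum(axis=axes), g.sum(axis=axes)

    out.grad_fn = grad_fn
    return out


# --------------------------------------------------------------------------
# Convolution kernels (shared by Conv2d and ConvTranspose2d)
# --------------------------------------------------------------------------

def _out_size(h, k, s, p, d):
    return (h + 2 * p - d * (k - 1) - 1) // s + 1


def _im2col(x, kh, kw, stride, pad, dil):
    n, c, h, w = x.shape
    ho = _out_size(h, kh, stride, pad, dil)
    wo = _out_size(w, kw, stride, pad, dil)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        r0 = i * dil
        for j in range(kw):
            c0 = j * dil
            cols[:, :, i, j] = xp[:, :, r0:r0 + ho * stride:stride,
                                  c0:c0 + wo * stride:stride]
    return cols, ho, wo


def _col2im(cols, x_shape, kh, kw, stride, pad, dil):
    n, c, h, w = x_shape
    ho, wo = cols.shape[-2:]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        r0 = i * dil
        for j in range(kw):
            c0 = j * dil
            xp[:, :, r0:r0 + ho * stride:stride, c0:c0 + wo * stride:stride] += (
                cols[:, :, i, j]
            )
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv_fwd(x, w, stride=1, pad=0, dil=1):
    co, ci, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, stride, pad, dil)
    n = x.shape[0]
    y = np.matmul(
        w.reshape(co, ci * kh * kw),
        cols.reshape(n, ci * kh * kw, ho * wo),
    )
    return y.reshape(n, co, ho, wo)


def conv_dx(gy, w, x_shape, stride=1, pad=0, dil=1):
    co, ci, kh, kw = w.shape
    n, _, ho, wo = gy.shape
    gcols = np.matmul(
        w.reshape(co, ci * kh * kw).T,
        gy.reshape(n, co, ho * wo),
    ).reshape(n, ci, kh, kw, ho, wo)
    return _col2im(gcols, x_shape, kh, kw, stride, pad, dil)


def conv_dw(x, gy, w_shape, stride=1, pad=0, dil=1):
    co, ci, kh, kw = w_shape
    cols, ho, wo = _im2col(x, kh, kw, stride, pad, dil)
    n = x.shape[0]
    gw = np.einsum(
        "nol,nkl->ok",
        gy.reshape(n, co, ho * wo),
        cols.reshape(n, ci * kh * kw, ho * wo),
        optimize=True,
    )
    return gw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, pad=0, dil=1) -> Tensor:
    y = conv_fwd(x.data, w.data, stride, pad, dil)
    if b is not None:
        y = y + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)
    out = Tensor(y, parents=parents)

    def grad_fn(g):
        gx = conv_dx(g, w.data, x.shape, stride, pad, dil)
        gw = conv_dw(x.data, g, w.shape, stride, pad, dil)
        if b is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    out.grad_fn = grad_fn
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=2, pad=1) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, kh, kw).

    Forward is the input-gradient kernel of the corresponding convolution,
    so output size is ``(H - 1) * stride - 2 * pad + kh``.
    """
    ci, co, kh, kw = w.shape
    n, _, h, wdt = x.shape
    ho = (h - 1) * stride - 2 * pad + kh
    wo = (wdt - 1) * stride - 2 * pad + kw
    y = conv_dx(x.data, w.data, (n, co, ho, wo), stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)
    out = Tensor(y, parents=parents)

    def grad_fn(g):
        gx = conv_fwd(g, w.data, stride, pad)
        gw = conv_dw(g, x.data, w.shape, stride, pad)
        if b is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    out.grad_fn = grad_fn
    return out


# --------------------------------------------------------------------------
# Pooling and resampling
# --------------------------------------------------------------------------

def maxpool2d(x: Tensor, k: int) -> Tensor:
    """Max pooling with kernel = stride = k; trailing remainder is dropped."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    xc = x.data[:, :, :ho * k, :wo * k]
    windows = xc.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(n, c, ho, wo, k * k)
    idx = windows.argmax(axis=-1)
    y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def grad_fn(g):
        gw_flat = np.zeros((n, c, ho, wo, k * k), dtype=DTYPE)
        np.put_along_axis(gw_flat, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :ho * k, :wo * k] = (
            gw_flat.reshape(n, c, ho, wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * k, wo * k)
        )
        return (gx,)

    out.grad_fn = grad_fn
    return out


def global_avgpool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))
    out.grad_fn = lambda g: (
        np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).astype(DTYPE),
    )
    return out


def upsample_to(x: Tensor, size) -> Tensor:
    """Nearest-neighbour upsampling to an arbitrary spatial size."""
    n, c, h, w = x.shape
    ht, wt = size
    ri = (np.arange(ht) * h // ht).astype(np.intp)
    ci = (np.arange(wt) * w // wt).astype(np.intp)
    out = Tensor(x.data[:, :, ri][:, :, :, ci], parents=(x,))

    def grad_fn(g):
        # scatter-add rows first, then columns, through a transposed view
        gx = np.zeros_like(x.data)
        row_sum = np.zeros((n, c, h, wt), dtype=DTYPE)
        np.add.at(row_sum, (slice(None), slice(None), ri), g)
        np.add.at(gx.transpose(0, 1, 3, 2), (slice(None), slice(None), ci),
                  row_sum.transpose(0, 1, 3, 2))
        return (gx,)

    out.grad_fn = grad_fn
    return out


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean, running_var, training: bool,
                momentum=0.1, eps=1e-5) -> Tensor:
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(DTYPE)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    out = Tensor(y, parents=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def grad_fn(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            gx = (inv[None, :, None, None] / m) * (
                m * gxhat
                - gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                - xhat * (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            )
        else:
            gx = gxhat * inv[None, :, None, None]
        return gx, ggamma, gbeta

    out.grad_fn = grad_fn
    return out


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

def weighted_softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                                   class_weights: np.ndarray) -> Tensor:
    """Mean over pixels of ``-w[y] * log softmax(logits)[y]``.

    ``logits`` is (N, K, ...) with labels (N, ...) of int class indices and
    ``class_weights`` of length K.
    """
    z = logits.data.astype(np.float64)
    z = np.moveaxis(z, 1, -1)  # (..., K)
    labels = np.asarray(labels)
    if labels.shape != z.shape[:-1]:
        raise ValueError(
            f"labels shape {labels.shape} does not match logits {z.shape[:-1]}"
        )
    w = np.asarray(class_weights, dtype=np.float64)
    if w.shape[0] != z.shape[-1]:
        raise ValueError(
            f"need {z.shape[-1]} class weights, got {w.shape[0]}"
        )
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax[..., 0] + np.log(np.exp(z - zmax).sum(axis=-1))
    picked = np.take_along_axis(z, labels[..., None], axis=-1)[..., 0]
    wy = w[labels]
    n = labels.size
    loss = float((wy * (lse - picked)).sum() / n)
    out = Tensor(np.asarray(loss), parents=(logits,))

    def grad_fn(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=-1, keepdims=True)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
        gz = (wy[..., None] * (p - onehot)) * (float(g) / n)
        return (np.moveaxis(gz, -1, 1).astype(DTYPE),)

    out.grad_fn = grad_fn
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all label slots."""
    z = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if t.shape != z.shape:
        raise ValueError(f"targets {t.shape} do not match logits {z.shape}")
    # stable: max(z,0) - z*t + log(1+exp(-|z|))
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    out = Tensor(np.asarray(loss), parents=(logits,))
    n = z.size

    def grad_fn(g):
        p = 1.0 / (1.0 + np.exp(-z))
        return (((p - t) * (float(g) / n)).astype(DTYPE),)

    out.grad_fn = grad_fn
    return out
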