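"""Differentiable primitives: conv, linear, ReLU, attention, Adam.

Conventions: images are NHWC, conv kernels are (k, k, C_in, C_out), token
batches are (B, S, C).  Every ``*_forward`` returns (output, cache) and the
matching ``*_backward`` consumes (d_output, cache) and returns input and
parameter gradients.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np


# ---------------------------------------------------------------- linear


def linear_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    y = x @ w
    if b is not None:
        y = y + b
    return y, (x, w, b is not None)


def linear_backward(dy: np.ndarray, cache):
    x, w, has_bias = cache
    dx = dy @ w.T
    # collapse any leading batch axes onto the contraction
    dw = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0) if has_bias else None
    return dx, dw, db


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy: np.ndarray, mask: np.ndarray):
    return dy * mask


# ---------------------------------------------------------------- conv 3x3


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 2, pad: int = 1):
    """3x3 convolution, NHWC layout, via column expansion."""
    k = w.shape[0]
    n, h, wd, c_in = x.shape
    c_out = w.shape[3]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (wd + 2 * pad - k) // stride + 1
    cols = np.empty((n, oh, ow, k, k, c_in), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, :, ki, kj, :] = xp[
                :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride, :
            ]
    flat = cols.reshape(n * oh * ow, k * k * c_in)
    y = (flat @ w.reshape(k * k * c_in, c_out) + b).reshape(n, oh, ow, c_out)
    cache = (flat, w, x.shape, stride, pad, (n, oh, ow))
    return y, cache


def conv2d_backward(dy: np.ndarray, cache):
    flat, w, x_shape, stride, pad, (n, oh, ow) = cache
    k, _, c_in, c_out = w.shape
    dy_flat = dy.reshape(n * oh * ow, c_out)
    dw = (flat.T @ dy_flat).reshape(w.shape)
    db = dy_flat.sum(axis=0)
    dcols = (dy_flat @ w.reshape(k * k * c_in, c_out).T).reshape(n, oh, ow, k, k, c_in)
    _, h, wd, _ = x_shape
    dxp = np.zeros((n, h + 2 * pad, wd + 2 * pad, c_in), dtype=dy.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride, :] += dcols[
                :, :, :, ki, kj, :
            ]
    dx = dxp[:, pad : pad + h, pad : pad + wd, :] if pad else dxp
    return dx, dw, db


def layernorm_forward(x: np.ndarray, eps: float = 1e-5):
    """Standardize over the last axis (no learnable affine)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    x_hat = (x - mu) * inv
    return x_hat, (x_hat, inv)


def layernorm_backward(dy: np.ndarray, cache):
    x_hat, inv = cache
    m1 = dy.mean(axis=-1, keepdims=True)
    m2 = (dy * x_hat).mean(axis=-1, keepdims=True)
    return inv * (dy - m1 - x_hat * m2)


# ------------------------------------------------------------- attention


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically safe softmax (max subtraction)."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_forward(q: np.ndarray, k: np.ndarray, v: np.ndarray):
    """softmax(QK^T / sqrt(d_k)) V over the key axis.

    Works for any leading batch/head axes; the last two axes are
    (sequence, channel).
    """
    if k.shape[-2] == 0:
        raise ValueError("attention requires at least one key")
    d_k = q.shape[-1]
    # python-float scale keeps the computation in the operands' dtype
    logits = q @ np.swapaxes(k, -1, -2) / float(np.sqrt(d_k))
    a = softmax(logits, axis=-1)
    out = a @ v
    return out, a, (q, k, v, a, d_k)


def attention_backward(dout: np.ndarray, cache):
    q, k, v, a, d_k = cache
    dv = np.swapaxes(a, -1, -2) @ dout
    da = dout @ np.swapaxes(v, -1, -2)
    ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
    dq = ds @ k / float(np.sqrt(d_k))
    dk = np.swapaxes(ds, -1, -2) @ q / float(np.sqrt(d_k))
    return dq, dk, dv


# ------------------------------------------------------------------ Adam


class AdamOptimizer:
    """Adaptive-moment gradient descent with the standard bias correction."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: Dict[str, np.ndarray] = {}
        self._v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            if g is None:
                continue
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def fan_in_uniform(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    """Scaled uniform initialization, bound 1/sqrt(fan_in)."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


__all__ = [
    "linear_forward",
    "linear_backward",
    "relu_forward",
    "relu_backward",
    "conv2d_forward",
    "conv2d_backward",
    "softmax",
    "attention_forward",
    "attention_backward",
    "AdamOptimizer",
    "fan_in_uniform",
]
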