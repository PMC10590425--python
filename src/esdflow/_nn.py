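"""Minimal NumPy neural-network primitives with hand-derived gradients.

The recognition stack (conv encoder, causal dilated TCN, attention head) is
small enough that explicit forward/backward functions over plain arrays are
simpler and more auditable than a general autodiff graph. Every backward
function here is validated against central finite differences in the test
suite.

Conventions: images are ``(B, C, H, W)`` float64; sequences are ``(T, d)``
(time-major). Parameters carry their own gradient and momentum buffers.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with accumulated gradient and SGD momentum state."""

    __slots__ = ("value", "grad", "velocity", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class SGD:
    """SGD with momentum: v <- mu*v + g; p <- p - lr*v."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p in self.params:
            p.velocity = self.momentum * p.velocity + p.grad
            p.value -= self.lr * p.velocity


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# Dense / activation
# ---------------------------------------------------------------------------


def linear_forward(x: np.ndarray, W: Parameter, b: Parameter):
    """x (N, in) -> (N, out); returns (out, cache)."""
    out = x @ W.value.T + b.value
    return out, (x, W, b)


def linear_backward(dout: np.ndarray, cache) -> np.ndarray:
    x, W, b = cache
    W.grad += dout.T @ x
    b.grad += dout.sum(axis=0)
    return dout @ W.value


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def l2_normalize_forward(x: np.ndarray, eps: float = 1e-12):
    """Row-wise unit normalization; returns (z, cache)."""
    norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + eps
    z = x / norm
    return z, (z, norm)


def l2_normalize_backward(dz: np.ndarray, cache) -> np.ndarray:
    z, norm = cache
    return (dz - z * (z * dz).sum(axis=1, keepdims=True)) / norm


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_forward(logits: np.ndarray, labels: np.ndarray):
    """Mean negative log-likelihood of the true class after softmax.

    Returns (loss, dlogits) — the gradient is cheap so it is produced eagerly.
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("labels outside the class range")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-300
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits


# ---------------------------------------------------------------------------
# 2-D convolution (im2col)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """x (B,C,H,W) -> patches (B, OH*OW, C*kh*kw) plus geometry."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, OH, OW, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, OH * OW, C * kh * kw)
    return np.ascontiguousarray(cols), (B, C, Hp, Wp, OH, OW)


def conv2d_forward(x: np.ndarray, W: Parameter, b: Parameter, stride: int, pad: int):
    """W.value has shape (F, C, kh, kw); returns (out (B,F,OH,OW), cache)."""
    F, C, kh, kw = W.value.shape
    cols, geom = _im2col(x, kh, kw, stride, pad)
    Wmat = W.value.reshape(F, C * kh * kw)
    out = cols @ Wmat.T + b.value  # (B, OH*OW, F)
    B, _, Hp, Wp, OH, OW = geom
    out = out.transpose(0, 2, 1).reshape(B, F, OH, OW)
    return out, (cols, geom, W, b, stride, pad)


def conv2d_backward(dout: np.ndarray, cache) -> np.ndarray:
    cols, geom, W, b, stride, pad = cache
    B, C, Hp, Wp, OH, OW = geom
    F, _, kh, kw = W.value.shape
    dflat = dout.reshape(B, F, OH * OW).transpose(0, 2, 1)  # (B, L, F)
    Wmat = W.value.reshape(F, C * kh * kw)
    W.grad += (
        dflat.reshape(-1, F).T @ cols.reshape(-1, C * kh * kw)
    ).reshape(W.value.shape)
    b.grad += dflat.sum(axis=(0, 1))
    dcols = dflat @ Wmat  # (B, L, C*kh*kw)
    dcols = dcols.reshape(B, OH, OW, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((B, C, Hp, Wp))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + OH * stride : stride, j : j + OW * stride : stride] += (
                dcols[:, :, :, :, i, j]
            )
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


# ---------------------------------------------------------------------------
# Causal dilated 1-D convolution over (T, d) sequences
# ---------------------------------------------------------------------------


def causal_conv1d_forward(
    x: np.ndarray, W: Parameter, b: Parameter, dilation: int
):
    """Causal dilated convolution: out[t] = b + sum_j W[j] @ x[t-(k-1-j)*dil].

    ``W.value`` has shape (k, d_out, d_in); missing past positions are zero
    (left zero-padding), so out[t] depends only on inputs <= t. Supports an
    optional leading batch axis: x may be (T, d) or (B, T, d).
    """
    k = W.value.shape[0]
    out = np.empty(x.shape[:-1] + (W.value.shape[1],))
    out[...] = b.value
    T = x.shape[-2]
    for j in range(k):
        off = (k - 1 - j) * dilation
        if off >= T:
            continue
        if off == 0:
            out += x @ W.value[j].T
        else:
            out[..., off:, :] += x[..., : T - off, :] @ W.value[j].T
    return out, (x, W, b, dilation)


def causal_conv1d_backward(dout: np.ndarray, cache) -> np.ndarray:
    x, W, b, dilation = cache
    k = W.value.shape[0]
    T = x.shape[-2]
    dx = np.zeros_like(x)
    b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
    for j in range(k):
        off = (k - 1 - j) * dilation
        if off >= T:
            continue
        if off == 0:
            W.grad[j] += dout.reshape(-1, dout.shape[-1]).T @ x.reshape(-1, x.shape[-1])
            dx += dout @ W.value[j]
        else:
            do = dout[..., off:, :]
            xi = x[..., : T - off, :]
            W.grad[j] += (
                do.reshape(-1, do.shape[-1]).T @ xi.reshape(-1, xi.shape[-1])
            )
            dx[..., : T - off, :] += do @ W.value[j]
    return dx


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (test oracle)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
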