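"""Causal dilated temporal convolution network (the temporal fusion module).

A stack of residual layers refines the spatial embedding sequence into
temporal embeddings ``m_i``. Layer ``l`` computes

    D_{l+1} = D_l + W_2 * ReLU(W_1 *_dilated D_l + b_1) + b_2

where ``*_dilated`` is a causal dilated convolution (left zero-padding of
``(k-1)*dilation``) and ``W_2`` a 1x1 convolution. Dilations double per layer
(1, 2, 4, ..., 2^{L-1}), so the receptive field is

    1 + (k-1) * sum_l dilation_l

which equals 512 for the default (k=2, 9 layers): the output at frame ``t``
depends on exactly the 511 preceding frames plus the current one. An input
1x1 projection maps the encoder dimension d to the TCN channel width d'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Parameter
from .encoder import SpatialEmbeddingSeq


@dataclass
class TcnConfig:
    num_layers: int = 9
    kernel_size: int = 2
    channels: int = 64  # d'
    input_dim: int = 64  # d (encoder embedding size)
    dilations: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        if not self.dilations:
            self.dilations = tuple(2**l for l in range(self.num_layers))
        if len(self.dilations) != self.num_layers:
            raise ValueError("need one dilation per layer")


def receptive_field(config: TcnConfig) -> int:
    """Closed-form dependency span: 1 + (k-1) * sum of dilations."""
    return 1 + (config.kernel_size - 1) * int(sum(config.dilations))


class TemporalConvNet:
    """Parameter container + forward/backward for the causal TCN."""

    def __init__(self, config: TcnConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d, dp = config.input_dim, config.channels
        k = config.kernel_size
        self.in_W = Parameter(_nn.he_init(rng, (dp, d), d), "tcn/in.W")
        self.in_b = Parameter(np.zeros(dp), "tcn/in.b")
        self.layers: list[dict[str, Parameter]] = []
        for l in range(config.num_layers):
            self.layers.append(
                {
                    "W1": Parameter(
                        _nn.he_init(rng, (k, dp, dp), k * dp), f"tcn/l{l}.W1"
                    ),
                    "b1": Parameter(np.zeros(dp), f"tcn/l{l}.b1"),
                    # small-gain residual-branch output keeps the deep stack
                    # near the identity at init (sum of L branches stays O(1))
                    "W2": Parameter(
                        0.1 * _nn.he_init(rng, (dp, dp), dp), f"tcn/l{l}.W2"
                    ),
                    "b2": Parameter(np.zeros(dp), f"tcn/l{l}.b2"),
                }
            )

    @property
    def parameters(self) -> list[Parameter]:
        ps = [self.in_W, self.in_b]
        for lw in self.layers:
            ps.extend(lw.values())
        return ps

    def forward(self, e: np.ndarray, want_cache: bool = False):
        """e: (T, d) or (B, T, d) spatial embeddings -> (.., T, d') temporal."""
        x = np.asarray(e, dtype=np.float64)
        D = x @ self.in_W.value.T + self.in_b.value
        caches = [("in", x)]
        for lw, dil in zip(self.layers, self.config.dilations):
            D, cache = residual_layer(D, lw, dil, want_cache=True)
            caches.append(("res", cache))
        if want_cache:
            return D, caches
        return D

    def backward(self, dout: np.ndarray, caches) -> np.ndarray:
        dD = dout
        for kind, cache in reversed(caches[1:]):
            dD = residual_layer_backward(dD, cache)
        kind, x = caches[0]
        self.in_W.grad += (
            dD.reshape(-1, dD.shape[-1]).T @ x.reshape(-1, x.shape[-1])
        )
        self.in_b.grad += dD.reshape(-1, dD.shape[-1]).sum(axis=0)
        return dD @ self.in_W.value

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.parameters}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.parameters:
            if p.name in arrays:
                p.value[...] = arrays[p.name]


def residual_layer(
    D: np.ndarray,
    weights: dict[str, Parameter],
    dilation: int,
    want_cache: bool = False,
):
    """One dilated residual layer: D + conv1x1(ReLU(causal_dilated_conv(D))).

    ``D`` is (T, d') or (B, T, d'); output index t depends only on inputs <= t.
    """
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    h, c1 = _nn.causal_conv1d_forward(D, weights["W1"], weights["b1"], dilation)
    h, rm = _nn.relu_forward(h)
    out = h @ weights["W2"].value.T + weights["b2"].value + D
    if want_cache:
        return out, (c1, rm, h, weights)
    return out


def residual_layer_backward(dout: np.ndarray, cache) -> np.ndarray:
    c1, rm, h, weights = cache
    dh = dout @ weights["W2"].value
    weights["W2"].grad += (
        dout.reshape(-1, dout.shape[-1]).T @ h.reshape(-1, h.shape[-1])
    )
    weights["b2"].grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
    dh = _nn.relu_backward(dh, rm)
    dD = _nn.causal_conv1d_backward(dh, c1)
    return dD + dout  # residual path


@dataclass
class TemporalEmbeddingSeq:
    """Per-frame temporal embeddings m_i for one case: a (T, d') array."""

    case_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (T, d')")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temporal embeddings must be finite")

    def __len__(self) -> int:
        return int(self.values.shape[0])


def tcn_forward(
    spatial: SpatialEmbeddingSeq, net: TemporalConvNet
) -> TemporalEmbeddingSeq:
    """Map a spatial embedding sequence to temporal embeddings."""
    if len(spatial) == 0:
        raise ValueError("empty spatial embedding sequence")
    return TemporalEmbeddingSeq(spatial.case_id, net.forward(spatial.values))


def measure_dependency_span(
    net: TemporalConvNet,
    T: int = 1024,
    seed: int = 0,
    perturbation: float = 1e3,
    tol: float = 1e-9,
    chunk: int = 64,
    dtype=np.float32,
) -> tuple[int, int]:
    """Empirical receptive field by single-frame input perturbation.

    Draws a random (T, d) input, perturbs each frame position one at a time
    (both +delta and -delta, so ReLU gating cannot mask a live path) and
    records whether the output at the last position changes. Returns
    ``(span, n_earlier)``: the number of consecutive influencing positions
    ending at T-1, and the number of *strictly earlier* influencing positions.
    """
    rng = np.random.default_rng(seed)
    d = net.config.input_dim
    base = rng.normal(size=(T, d)).astype(dtype)
    ref = np.asarray(net.forward(base.astype(np.float64)))[-1]
    influenced = np.zeros(T, dtype=bool)
    for start in range(0, T, chunk):
        stop = min(start + chunk, T)
        for sign in (1.0, -1.0):
            todo = [p for p in range(start, stop) if not influenced[p]]
            if not todo:
                continue
            batch = np.repeat(base[None, :, :], len(todo), axis=0)
            for i, pos in enumerate(todo):
                batch[i, pos, :] += sign * perturbation
            out = np.asarray(net.forward(batch.astype(np.float64)))[:, -1, :]
            hit = np.abs(out - ref).max(axis=1) > tol
            influenced[np.asarray(todo)[hit]] = True
    idx = np.flatnonzero(influenced)
    span = int(T - idx.min()) if idx.size else 0
    n_earlier = int(np.sum(influenced[:-1]))
    return span, n_earlier
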