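"""Scaled dot-product attention head producing per-frame phase probabilities.

The spatial embedding ``e_t`` is reduced to a query ``ê_t`` of the TCN
channel width d'; the last ``n`` temporal embeddings ``M_t = [m_{t-n+1..t}]``
serve as keys and values:

    attn(ê_t, M_t) = softmax( (W_q ê_t) (W_k M_t)^T / sqrt(d') ) W_v M_t

A final 4-way linear classifier maps the attention output to logits and the
outer softmax yields ``p_t``. Early in a stream the window is capped at
``t+1`` frames. Single head, single layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Parameter
from .workflow import NUM_PHASES, Phase


@dataclass
class HeadConfig:
    window: int = 30  # n, number of recent temporal embeddings attended over
    query_dim: int = 64  # d (spatial embedding size)
    channels: int = 64  # d' (temporal embedding size)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class PhaseProbabilities:
    """A 4-way probability vector over the phases."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (NUM_PHASES,):
            raise ValueError("p must be a 4-vector")
        if (self.p < 0).any() or abs(float(self.p.sum()) - 1.0) > 1e-6:
            raise ValueError("p must be a probability simplex vector")


class AttentionHead:
    """Parameters + forward/backward for the attention classifier."""

    def __init__(self, config: HeadConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d, dp = config.query_dim, config.channels
        self.red_W = Parameter(_nn.he_init(rng, (dp, d), d), "head/red.W")
        self.red_b = Parameter(np.zeros(dp), "head/red.b")
        self.Wq = Parameter(_nn.he_init(rng, (dp, dp), dp), "head/Wq")
        self.Wk = Parameter(_nn.he_init(rng, (dp, dp), dp), "head/Wk")
        self.Wv = Parameter(_nn.he_init(rng, (dp, dp), dp), "head/Wv")
        self.cls_W = Parameter(_nn.he_init(rng, (NUM_PHASES, dp), dp), "head/cls.W")
        self.cls_b = Parameter(np.zeros(NUM_PHASES), "head/cls.b")

    @property
    def parameters(self) -> list[Parameter]:
        return [self.red_W, self.red_b, self.Wq, self.Wk, self.Wv,
                self.cls_W, self.cls_b]

    # -- batched forward over a whole sequence -------------------------------

    def forward_sequence(self, E: np.ndarray, M: np.ndarray, want_cache=False):
        """Per-frame attention over sliding windows of temporal embeddings.

        ``E``: (T, d) spatial embeddings (queries); ``M``: (T, d') temporal
        embeddings. Frame t attends over ``M[max(0, t-n+1) : t+1]``. Returns
        logits (T, 4).
        """
        n = self.config.window
        dp = self.config.channels
        T = E.shape[0]
        Ehat = E @ self.red_W.value.T + self.red_b.value  # (T, d')
        Q = Ehat @ self.Wq.value.T
        K = M @ self.Wk.value.T
        V = M @ self.Wv.value.T
        idx = np.arange(T)[:, None] - (n - 1) + np.arange(n)[None, :]  # (T, n)
        mask = idx >= 0
        idx_c = np.clip(idx, 0, T - 1)
        Kw = K[idx_c]  # (T, n, d')
        Vw = V[idx_c]
        scores = np.einsum("td,tnd->tn", Q, Kw) / np.sqrt(dp)
        scores = np.where(mask, scores, -np.inf)
        A = _nn.softmax(scores, axis=1)  # (T, n)
        ctx = np.einsum("tn,tnd->td", A, Vw)
        logits = ctx @ self.cls_W.value.T + self.cls_b.value
        if want_cache:
            return logits, (E, M, Ehat, Q, K, V, idx_c, mask, A, ctx)
        return logits

    def backward_sequence(self, dlogits: np.ndarray, cache):
        """Returns (dE, dM) and accumulates parameter gradients."""
        E, M, Ehat, Q, K, V, idx_c, mask, A, ctx = cache
        dp = self.config.channels
        T, n = idx_c.shape
        self.cls_W.grad += dlogits.T @ ctx
        self.cls_b.grad += dlogits.sum(axis=0)
        dctx = dlogits @ self.cls_W.value  # (T, d')
        Vw = V[idx_c]
        Kw = K[idx_c]
        dA = np.einsum("td,tnd->tn", dctx, Vw)
        dVw = A[:, :, None] * dctx[:, None, :]  # (T, n, d')
        # softmax backward per row (masked entries have A=0)
        dscores = A * (dA - (A * dA).sum(axis=1, keepdims=True))
        dscores = np.where(mask, dscores, 0.0) / np.sqrt(dp)
        dQ = np.einsum("tn,tnd->td", dscores, Kw)
        dKw = dscores[:, :, None] * Q[:, None, :]
        dK = np.zeros_like(K)
        dV = np.zeros_like(V)
        flat_idx = idx_c.ravel()
        np.add.at(dK, flat_idx, dKw.reshape(-1, dp) * mask.ravel()[:, None])
        np.add.at(dV, flat_idx, dVw.reshape(-1, dp) * mask.ravel()[:, None])
        dM = dK @ self.Wk.value + dV @ self.Wv.value
        self.Wk.grad += dK.T @ M
        self.Wv.grad += dV.T @ M
        dEhat = dQ @ self.Wq.value
        self.Wq.grad += dQ.T @ Ehat
        self.red_W.grad += dEhat.T @ E
        self.red_b.grad += dEhat.sum(axis=0)
        dE = dEhat @ self.red_W.value
        return dE, dM

    def probabilities(self, E: np.ndarray, M: np.ndarray) -> np.ndarray:
        """(T, 4) phase probabilities for a whole sequence."""
        return _nn.softmax(self.forward_sequence(E, M), axis=1)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.parameters}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.parameters:
            if p.name in arrays:
                p.value[...] = arrays[p.name]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def reduce_query(e_t: np.ndarray, head: AttentionHead) -> np.ndarray:
    """Linear reduction of a spatial embedding to the temporal width d'."""
    e_t = np.asarray(e_t, dtype=np.float64)
    if e_t.shape != (self_dim := head.config.query_dim,):
        raise ValueError(f"expected a {self_dim}-vector, got shape {e_t.shape}")
    return head.red_W.value @ e_t + head.red_b.value


def attend(
    e_hat: np.ndarray, M_t: np.ndarray, head: AttentionHead
) -> tuple[np.ndarray, PhaseProbabilities]:
    """Single-frame attention: returns (attention output, p_t).

    ``M_t`` holds the min(t+1, n) most recent temporal embeddings, most
    recent last. Attention weights sum to 1 by construction.
    """
    M_t = np.asarray(M_t, dtype=np.float64)
    if M_t.ndim != 2 or M_t.shape[0] == 0:
        raise ValueError("M_t must be a nonempty (n, d') array")
    dp = head.config.channels
    q = head.Wq.value @ np.asarray(e_hat, dtype=np.float64)
    K = M_t @ head.Wk.value.T
    V = M_t @ head.Wv.value.T
    scores = K @ q / np.sqrt(dp)
    w = _nn.softmax(scores)
    out = w @ V
    logits = head.cls_W.value @ out + head.cls_b.value
    return out, PhaseProbabilities(_nn.softmax(logits))


def predict_phase(
    p: PhaseProbabilities | np.ndarray,
    mode: str = "argmax",
    thresholds: np.ndarray | None = None,
) -> Phase:
    """Hard phase decision from a probability vector.

    ``argmax`` breaks ties toward the lowest canonical phase code. ``youden``
    picks, among phases whose probability passes the per-phase threshold, the
    one with the largest margin ``p_k - threshold_k``; if none passes it
    falls back to argmax.
    """
    if isinstance(p, PhaseProbabilities):
        vec = p.p
    else:
        vec = PhaseProbabilities(np.asarray(p, dtype=np.float64)).p
    if mode == "argmax":
        return Phase(int(np.argmax(vec)))
    if mode == "youden":
        if thresholds is None:
            raise ValueError("youden mode requires per-phase thresholds")
        thresholds = np.asarray(thresholds, dtype=np.float64)
        margins = vec - thresholds
        passing = margins >= 0
        if not passing.any():
            return Phase(int(np.argmax(vec)))
        masked = np.where(passing, margins, -np.inf)
        return Phase(int(np.argmax(masked)))
    raise ValueError(f"unknown decision mode {mode!r}")
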