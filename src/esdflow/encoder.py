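"""Frame-wise spatial encoder trained with a joint contrastive + CE objective.

The encoder ``G`` maps each video frame to a d-dimensional spatial embedding
``e_i``. During stage-1 training two linear projection heads (with a ReLU in
between and unit normalization at the output) feed a supervised contrastive
loss that pulls same-phase frames together and pushes different-phase frames
apart, while a linear classifier on the backbone embedding adds a
cross-entropy term. For deployment the projection heads are pruned and only
the backbone embedding is used downstream.

Two readings of the contrastive denominator are provided:

* ``"paper_literal"`` — the denominator sums over different-phase frames
  ``N(i)`` only. With this form the per-pair term is ``-s_in + logsumexp_N``,
  which is unbounded below as positive similarity grows.
* ``"all_others"`` — the standard supervised-contrastive denominator over all
  non-anchor frames ``A(i) ∪ N(i)``, which is nonnegative with one positive.

The default follows the literal formula; the choice is a config field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Parameter
from .workflow import NUM_PHASES, VideoStream

#: backbone name -> list of (out_channels_or_None_for_embedding, kernel, stride, pad)
_BACKBONES: dict[str, list[tuple[int | None, int, int, int]]] = {
    # 4 strided blocks; global average pool to the embedding
    "small-conv": [(16, 5, 4, 2), (32, 3, 2, 1), (64, 3, 2, 1), (None, 3, 2, 1)],
    # 3 strided blocks for very small fixtures
    "tiny-conv": [(8, 5, 4, 2), (16, 3, 2, 1), (None, 3, 2, 1)],
}


@dataclass
class EncoderConfig:
    backbone: str = "small-conv"
    embedding_dim: int = 64
    projection_dims: tuple[int, int] = (64, 32)
    temperature: float = 0.1
    contrastive_denominator: str = "paper_literal"
    input_hw: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; registered: "
                f"{sorted(_BACKBONES)}"
            )
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.contrastive_denominator not in ("paper_literal", "all_others"):
            raise ValueError("contrastive_denominator must be "
                             "'paper_literal' or 'all_others'")


@dataclass
class SpatialEmbeddingSeq:
    """Per-frame spatial embeddings e_i for one case: a (T, d) array."""

    case_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (T, d)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embeddings must be finite")

    def __len__(self) -> int:
        return int(self.values.shape[0])


class SpatialEncoder:
    """Convolutional frame encoder with prunable projection heads."""

    def __init__(self, config: EncoderConfig, seed: int = 0) -> None:
        self.config = config
        self.pruned = False
        rng = np.random.default_rng(seed)
        self.conv_params: list[tuple[Parameter, Parameter]] = []
        c_in = 3
        for i, (c_out, k, s, p) in enumerate(_BACKBONES[config.backbone]):
            c = c_out if c_out is not None else config.embedding_dim
            fan = c_in * k * k
            W = Parameter(_nn.he_init(rng, (c, c_in, k, k), fan), f"conv{i}.W")
            b = Parameter(np.zeros(c), f"conv{i}.b")
            self.conv_params.append((W, b))
            c_in = c
        d = config.embedding_dim
        h1, h2 = config.projection_dims
        self.proj1_W = Parameter(_nn.he_init(rng, (h1, d), d), "proj1.W")
        self.proj1_b = Parameter(np.zeros(h1), "proj1.b")
        self.proj2_W = Parameter(_nn.he_init(rng, (h2, h1), h1), "proj2.W")
        self.proj2_b = Parameter(np.zeros(h2), "proj2.b")
        self.cls_W = Parameter(_nn.he_init(rng, (NUM_PHASES, d), d), "cls.W")
        self.cls_b = Parameter(np.zeros(NUM_PHASES), "cls.b")

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def backbone_parameters(self) -> list[Parameter]:
        return [p for pair in self.conv_params for p in pair]

    @property
    def head_parameters(self) -> list[Parameter]:
        if self.pruned:
            return []
        return [self.proj1_W, self.proj1_b, self.proj2_W, self.proj2_b]

    @property
    def parameters(self) -> list[Parameter]:
        ps = self.backbone_parameters + self.head_parameters
        if not self.pruned:
            ps += [self.cls_W, self.cls_b]
        return ps

    @property
    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    # -- forward / backward ---------------------------------------------------

    def _check_input(self, frames: np.ndarray) -> None:
        H, W = self.config.input_hw
        if frames.shape[-3:] != (H, W, 3):
            raise ValueError(
                f"frame shape {frames.shape[-3:]} does not match encoder input "
                f"spec {(H, W, 3)}"
            )

    def forward_backbone(self, x: np.ndarray):
        """x: (B, H, W, 3) in [0, 255] or [0, 1]; returns (e (B, d), cache)."""
        self._check_input(x)
        if np.issubdtype(np.asarray(x).dtype, np.integer):  # raw 8-bit input
            x = np.asarray(x, dtype=np.float64) / 255.0
        else:
            x = np.asarray(x, dtype=np.float64)
        x = (x - 0.5).transpose(0, 3, 1, 2)  # (B, 3, H, W), centered
        caches = []
        for W, b in self.conv_params:
            _, _, _, k = W.value.shape
            stride, pad = _conv_geometry(self.config.backbone, W, self.conv_params)
            x, cc = _nn.conv2d_forward(x, W, b, stride, pad)
            x, rc = _nn.relu_forward(x)
            caches.append((cc, rc))
        B, C = x.shape[0], x.shape[1]
        spatial = x.shape[2] * x.shape[3]
        e = x.mean(axis=(2, 3))  # global average pool -> (B, d)
        return e, (caches, x.shape, spatial)

    def backward_backbone(self, de: np.ndarray, cache) -> None:
        caches, shape, spatial = cache
        dx = np.broadcast_to(
            de[:, :, None, None] / spatial, shape
        ).copy()
        for cc, rc in reversed(caches):
            dx = _nn.relu_backward(dx, rc)
            dx = _nn.conv2d_backward(dx, cc)

    def project(self, e: np.ndarray):
        """Projection heads: e -> unit-normalized contrastive embedding z."""
        if self.pruned:
            raise RuntimeError("projection heads have been pruned")
        h, c1 = _nn.linear_forward(e, self.proj1_W, self.proj1_b)
        h, rm = _nn.relu_forward(h)
        u, c2 = _nn.linear_forward(h, self.proj2_W, self.proj2_b)
        z, nc = _nn.l2_normalize_forward(u)
        return z, (c1, rm, c2, nc)

    def project_backward(self, dz: np.ndarray, cache) -> np.ndarray:
        c1, rm, c2, nc = cache
        du = _nn.l2_normalize_backward(dz, nc)
        dh = _nn.linear_backward(du, c2)
        dh = _nn.relu_backward(dh, rm)
        return _nn.linear_backward(dh, c1)

    def classify(self, e: np.ndarray):
        return _nn.linear_forward(e, self.cls_W, self.cls_b)

    def embed_frames(self, frames: np.ndarray, batch: int = 256) -> np.ndarray:
        """Evaluation-mode embedding of (T, H, W, 3) frames -> (T, d)."""
        outs = []
        for i in range(0, frames.shape[0], batch):
            e, _ = self.forward_backbone(frames[i : i + batch])
            outs.append(e)
        return np.concatenate(outs, axis=0)

    # -- pruning --------------------------------------------------------------

    def prune_heads(self) -> "SpatialEncoder":
        """Remove the two linear projection heads (and the stage-1 classifier).

        Backbone weights are untouched; calling twice is an error.
        """
        if self.pruned:
            raise RuntimeError("encoder is already pruned")
        self.pruned = True
        return self

    # -- (de)serialization ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"enc/{p.name}": p.value for p in self.backbone_parameters}
        if not self.pruned:
            for p in self.head_parameters + [self.cls_W, self.cls_b]:
                out[f"enc/{p.name}"] = p.value
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.parameters:
            key = f"enc/{p.name}"
            if key in arrays:
                p.value[...] = arrays[key]


def _conv_geometry(backbone: str, W: Parameter, conv_params) -> tuple[int, int]:
    idx = [id(w) for w, _ in conv_params].index(id(W))
    _, _, stride, pad = _BACKBONES[backbone][idx]
    return stride, pad


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def embed(frames: VideoStream, encoder: SpatialEncoder) -> SpatialEmbeddingSeq:
    """Evaluation-mode per-frame embeddings for a whole video."""
    if len(frames) == 0:
        raise ValueError("video has no frames")
    values = encoder.embed_frames(frames.frames)
    return SpatialEmbeddingSeq(frames.case_id, values)


def supcon_loss(
    embeddings: np.ndarray,
    labels: np.ndarray,
    temperature: float,
    denominator_mode: str = "paper_literal",
    return_grad: bool = False,
    anchor_indices: np.ndarray | None = None,
):
    """Supervised contrastive loss over one batch of (normalized) embeddings.

    ``L = sum_i (-1/|A(i)|) sum_{n in A(i)} log[exp(e_i.e_n/tau) /
    sum_{a in D(i)} exp(e_i.e_a/tau)]`` where ``A(i)``/``N(i)`` index
    same-/different-phase frames and ``D(i)`` is ``N(i)``
    (``paper_literal``) or ``A(i) ∪ N(i)`` (``all_others``). Anchors with an
    empty ``A(i)`` or ``N(i)`` are skipped; a batch where every anchor is
    skipped (e.g. a single-class batch) is an error. ``anchor_indices``
    restricts the outer sum to a subset of rows (useful for evaluating the
    per-anchor formula directly); by default every row is an anchor.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if denominator_mode not in ("paper_literal", "all_others"):
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    z = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    B = z.shape[0]
    if labels.shape != (B,):
        raise ValueError("labels must align with embedding rows")
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    diff = labels[:, None] != labels[None, :]
    n_pos = same.sum(axis=1)
    n_neg = diff.sum(axis=1)
    valid = (n_pos >= 1) & (n_neg >= 1)
    if anchor_indices is not None:
        keep = np.zeros(B, dtype=bool)
        keep[np.asarray(anchor_indices)] = True
        valid &= keep
    if not valid.any():
        raise ValueError("no valid anchors: every anchor lacks a positive or "
                         "a negative (single-class batch?)")
    s = z @ z.T / temperature
    denom_mask = diff if denominator_mode == "paper_literal" else (same | diff)
    # stable logsumexp over the denominator set, per anchor
    s_masked = np.where(denom_mask, s, -np.inf)
    m = s_masked.max(axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)  # rows with empty D are invalid anyway
    with np.errstate(divide="ignore", invalid="ignore"):
        lse = m[:, 0] + np.log(np.exp(s_masked - m).sum(axis=1))
    pos_mean = np.where(valid, (s * same).sum(axis=1) / np.maximum(n_pos, 1), 0.0)
    per_anchor = -pos_mean + lse
    loss = float(per_anchor[valid].sum())
    if not return_grad:
        return loss
    g = np.zeros_like(s)
    sm = np.exp(s_masked - m)
    with np.errstate(invalid="ignore"):
        sm = sm / np.maximum(sm.sum(axis=1, keepdims=True), 1e-300)
    g[valid] = sm[valid] - (same[valid] / n_pos[valid, None])
    dz = (g + g.T) @ z / temperature
    return loss, dz, int(valid.sum())


def ce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true phase after softmax."""
    loss, _ = _nn.cross_entropy_forward(np.asarray(logits, float), labels)
    return loss


def prune_heads(encoder: SpatialEncoder) -> SpatialEncoder:
    """Module-level alias for :meth:`SpatialEncoder.prune_heads`."""
    return encoder.prune_heads()


def centroid_probe_accuracy(
    train_emb: np.ndarray,
    train_labels: np.ndarray,
    test_emb: np.ndarray,
    test_labels: np.ndarray,
) -> float:
    """Nearest-centroid probe: a training-free check of embedding quality."""
    classes = np.unique(train_labels)
    centroids = np.stack([train_emb[train_labels == c].mean(axis=0) for c in classes])
    d2 = ((test_emb[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[np.argmin(d2, axis=1)]
    return float((pred == test_labels).mean())
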