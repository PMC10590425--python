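"""Two-stage optimization and chronological cross-validation.

Stage 1 trains the spatial encoder on uniformly sampled frames with the
joint contrastive + cross-entropy objective. The encoder is then pruned and
frozen, all spatial embeddings are precomputed once, and stage 2 trains the
TCN + attention head end-to-end with per-frame cross-entropy, consuming one
whole video's embedding sequence per iteration. The final-iteration model is
the released model — there is no early stopping.

Cross-validation folds are chronological: cases are ordered by date and case
at position i goes to fold ``i mod k`` (equal-interval striding), so every
fold spans the full date range. For 47 cases and k=5 this yields fold sizes
(10, 10, 9, 9, 9).

Two schedule presets exist:

* ``full`` — stage 1: 8000 iterations, batch 128, lr 5e-4 (/10 at 6000);
  stage 2: 4000 iterations, lr 5e-3 (/10 at 1500 and 2500) — sized for
  real multi-hour surgical video corpora;
* ``desk`` — iteration counts divided by ~25 and batch by 4, with learning
  rates chosen for the small default backbone, so the full pipeline runs in
  minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import SGD, clip_grad_norm, cross_entropy_forward
from .attention import AttentionHead, HeadConfig
from .encoder import (
    EncoderConfig,
    SpatialEncoder,
    supcon_loss,
)
from .models import ModelBundle
from .synthetic import SyntheticCase
from .tcn import TcnConfig, TemporalConvNet
from .workflow import AnnotationTrack, PredictionTrack, VideoStream


@dataclass
class StageSchedule:
    iterations: int
    lr: float
    lr_drop_iters: tuple[int, ...]
    drop_factor: float = 10.0
    batch_size: int | None = None  # stage 1 only
    #: global gradient-norm ceiling; keeps SGD-with-momentum from the
    #: dead-ReLU collapse a single oversized step can trigger
    clip_grad_norm: float = 5.0

    def __post_init__(self) -> None:
        if any(d >= self.iterations for d in self.lr_drop_iters):
            raise ValueError("lr drop iterations must precede the final iteration")

    def lr_at(self, iteration: int) -> float:
        drops = sum(1 for d in self.lr_drop_iters if iteration >= d)
        return self.lr / (self.drop_factor**drops)


@dataclass
class TrainSchedule:
    stage1: StageSchedule = field(
        default_factory=lambda: StageSchedule(8000, 5e-4, (6000,), 10.0, 128)
    )
    stage2: StageSchedule = field(
        default_factory=lambda: StageSchedule(4000, 5e-3, (1500, 2500), 10.0)
    )
    momentum: float = 0.9


def desk_schedule() -> TrainSchedule:
    """Desk-scale preset: the full pipeline in minutes on one CPU."""
    return TrainSchedule(
        stage1=StageSchedule(320, 5e-3, (240,), 10.0, 32),
        stage2=StageSchedule(160, 1e-3, (100, 140), 10.0),
    )


def get_schedule(preset: str) -> TrainSchedule:
    if preset == "full":
        return TrainSchedule()
    if preset == "desk":
        return desk_schedule()
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """fold index per case, cases listed in chronological order."""

    case_ids: list[str]
    fold_of: np.ndarray  # (n_cases,) ints in [0, k)
    k: int

    def fold_sizes(self) -> tuple[int, ...]:
        return tuple(int((self.fold_of == f).sum()) for f in range(self.k))

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def chronological_folds(
    cases: list[AnnotationTrack] | list[str], k: int, dates: list[str] | None = None
) -> FoldAssignment:
    """Equal-interval (strided) chronological assignment: position i -> i mod k.

    ``cases`` may be tracks carrying metadata dates, or bare case ids with an
    explicit parallel ``dates`` list. Cases are sorted by date first, so each
    fold spans the full date range.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if len(cases) < k:
        raise ValueError(f"cannot split {len(cases)} cases into {k} folds")
    if cases and isinstance(cases[0], AnnotationTrack):
        ids = [c.case_id for c in cases]  # type: ignore[union-attr]
        dates = [c.metadata.date or "" for c in cases]  # type: ignore[union-attr]
    else:
        ids = list(cases)  # type: ignore[arg-type]
        dates = dates if dates is not None else [""] * len(ids)
    order = np.argsort(np.asarray(dates, dtype=object), kind="stable")
    ordered_ids = [ids[i] for i in order]
    fold_of = np.arange(len(ids)) % k
    return FoldAssignment(ordered_ids, fold_of, k)


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------


def train_stage1(
    cases: list[SyntheticCase] | list[tuple[VideoStream, AnnotationTrack]],
    config: EncoderConfig,
    schedule: StageSchedule,
    seed: int = 0,
) -> tuple[SpatialEncoder, list[float]]:
    """Train the spatial encoder; returns (encoder, per-iteration loss history).

    Frames are sampled uniformly over (case, frame) pairs. The objective is
    the per-anchor mean of the supervised contrastive loss plus the mean
    cross-entropy of the linear phase classifier. Deterministic given seed.
    """
    pairs = _as_pairs(cases)
    if not pairs:
        raise ValueError("no training cases")
    frames = np.concatenate([v.frames for v, _ in pairs], axis=0)
    labels = np.concatenate([t.labels for _, t in pairs])
    if np.unique(labels).size < 2:
        raise ValueError("stage-1 training needs at least 2 phases in the data")
    rng = np.random.default_rng(seed)
    encoder = SpatialEncoder(config, seed=int(rng.integers(2**31)))
    opt = SGD(encoder.parameters, schedule.lr)
    history: list[float] = []
    batch = schedule.batch_size or 32
    n = frames.shape[0]
    for it in range(schedule.iterations):
        opt.lr = schedule.lr_at(it)
        idx = rng.integers(0, n, size=batch)
        x, y = frames[idx], labels[idx]
        opt.zero_grad()
        e, bb_cache = encoder.forward_backbone(x)
        z, proj_cache = encoder.project(e)
        logits, cls_cache = encoder.classify(e)
        ce, dlogits = cross_entropy_forward(logits, y)
        try:
            con, dz, n_anchors = supcon_loss(
                z, y, config.temperature, config.contrastive_denominator,
                return_grad=True,
            )
            con_mean = con / n_anchors
            dz = dz / n_anchors
        except ValueError:  # single-class batch: contrastive term undefined
            con_mean, dz = 0.0, None
        de = _linear_backward_into(dlogits, cls_cache)
        if dz is not None:
            de = de + encoder.project_backward(dz, proj_cache)
        encoder.backward_backbone(de, bb_cache)
        if schedule.clip_grad_norm:
            clip_grad_norm(opt.params, schedule.clip_grad_norm)
        opt.step()
        history.append(con_mean + ce)
    return encoder, history


def _linear_backward_into(dout, cache):
    from ._nn import linear_backward

    return linear_backward(dout, cache)


def _as_pairs(cases) -> list[tuple[VideoStream, AnnotationTrack]]:
    out = []
    for c in cases:
        if isinstance(c, SyntheticCase):
            out.append((c.video, c.track))
        else:
            out.append(tuple(c))
    return out


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------


def train_stage2(
    encoder: SpatialEncoder,
    cases: list[SyntheticCase] | list[tuple[VideoStream, AnnotationTrack]],
    tcn_config: TcnConfig,
    head_config: HeadConfig,
    schedule: StageSchedule,
    seed: int = 0,
) -> tuple[ModelBundle, list[float]]:
    """Train TCN + head on frozen-encoder embeddings; returns (bundle, history).

    The encoder must already be pruned (frozen contract): its weights are
    read, never written. Spatial embeddings are precomputed once; each
    iteration consumes one whole video's embedding sequence and minimizes
    per-frame cross-entropy on p_t.
    """
    if not encoder.pruned:
        raise ValueError("stage 2 requires a pruned (frozen) encoder")
    pairs = _as_pairs(cases)
    if not pairs:
        raise ValueError("no training cases")
    emb = [encoder.embed_frames(v.frames) for v, _ in pairs]
    labels = [t.labels for _, t in pairs]
    rng = np.random.default_rng(seed)
    tcn = TemporalConvNet(tcn_config, seed=int(rng.integers(2**31)))
    head = AttentionHead(head_config, seed=int(rng.integers(2**31)))
    opt = SGD(tcn.parameters + head.parameters, schedule.lr)
    history: list[float] = []
    for it in range(schedule.iterations):
        opt.lr = schedule.lr_at(it)
        vi = int(rng.integers(len(pairs)))
        E, y = emb[vi], labels[vi]
        opt.zero_grad()
        M, tcn_cache = tcn.forward(E, want_cache=True)
        logits, head_cache = head.forward_sequence(E, M, want_cache=True)
        loss, dlogits = cross_entropy_forward(logits, y)
        dE_head, dM = head.backward_sequence(dlogits, head_cache)
        tcn.backward(dM, tcn_cache)
        if schedule.clip_grad_norm:
            clip_grad_norm(opt.params, schedule.clip_grad_norm)
        opt.step()
        history.append(loss)
    return ModelBundle(encoder, tcn, head), history


def train_full(
    cases,
    enc_config: EncoderConfig,
    tcn_config: TcnConfig,
    head_config: HeadConfig,
    schedule: TrainSchedule,
    seed: int = 0,
) -> tuple[ModelBundle, dict[str, list[float]]]:
    """Both stages on one training set (also the `train-final` retrain mode)."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2))
    encoder, h1 = train_stage1(cases, enc_config, schedule.stage1, seed=s1)
    encoder.prune_heads()
    bundle, h2 = train_stage2(
        encoder, cases, tcn_config, head_config, schedule.stage2, seed=s2
    )
    return bundle, {"stage1": h1, "stage2": h2}


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def run_cross_validation(
    cases: list[SyntheticCase] | list[tuple[VideoStream, AnnotationTrack]],
    k: int,
    enc_config: EncoderConfig,
    tcn_config: TcnConfig,
    head_config: HeadConfig,
    schedule: TrainSchedule,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> dict:
    """Chronological k-fold cross-validation; returns predictions + metrics.

    Trains on k-1 folds, evaluates on the held-out fold, rotates. Emits
    per-case prediction tracks and the pooled metric tables of
    :func:`esdflow.metrics.evaluate_cases`. ``shuffle_labels=True`` permutes
    the training labels (test labels untouched) as a negative control: the
    resulting AUROCs should hover around chance.
    """
    from .metrics import evaluate_cases
    from .streaming import offline_predict

    pairs = _as_pairs(cases)
    tracks = [t for _, t in pairs]
    folds = chronological_folds(tracks, k)
    id_to_idx = {t.case_id: i for i, t in enumerate(tracks)}
    ordered = [id_to_idx[cid] for cid in folds.case_ids]
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(k + 1)]
    shuffle_rng = np.random.default_rng(fold_seeds[-1])
    predictions: list[PredictionTrack] = []
    truths: list[AnnotationTrack] = []
    per_fold = []
    for fold in range(k):
        train_idx = [ordered[i] for i in folds.train_indices(fold)]
        test_idx = [ordered[i] for i in folds.test_indices(fold)]
        train_pairs = [pairs[i] for i in train_idx]
        if shuffle_labels:
            train_pairs = [
                (v, AnnotationTrack(
                    t.case_id, t.fps,
                    shuffle_rng.permutation(t.labels), t.metadata))
                for v, t in train_pairs
            ]
        bundle, _ = train_full(
            train_pairs, enc_config, tcn_config, head_config, schedule,
            seed=fold_seeds[fold],
        )
        fold_preds = [offline_predict(pairs[i][0], bundle) for i in test_idx]
        predictions.extend(fold_preds)
        truths.extend(pairs[i][1] for i in test_idx)
        per_fold.append({"fold": fold, "test_cases":
                         [pairs[i][1].case_id for i in test_idx]})
    results = evaluate_cases(predictions, truths)
    results["folds"] = per_fold
    results["predictions"] = predictions
    results["truths"] = truths
    return results
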