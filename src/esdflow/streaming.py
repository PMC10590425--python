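"""Real-time streaming inference with a bounded FIFO embedding queue.

The stream keeps only the spatial embeddings inside the TCN's receptive
field R (default 512): when ``e_i`` falls out of the field it graduates from
the queue, so state is O(R) regardless of stream length. Each pushed frame
is embedded, the causal TCN is run over the queue contents to produce the
current temporal embedding ``m_t`` (exact, because the queue spans the whole
receptive field of position t), and the attention head attends over the last
``min(t+1, n)`` temporal embeddings. Streaming predictions are therefore
equivalent to offline causal inference frame by frame; the equivalence is a
tested invariant, not an approximation.

Per-stage wall-clock latencies (encoder / fusion / head) are recorded on
every push for logging; they are hardware facts, never asserted.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .attention import attend, predict_phase
from .encoder import SpatialEmbeddingSeq, embed
from .models import ModelBundle
from .tcn import receptive_field
from .workflow import Phase, PredictionTrack, VideoStream


@dataclass
class FramePrediction:
    """Prediction and per-stage latency for one pushed frame."""

    frame_index: int
    probs: np.ndarray  # (4,)
    label: Phase
    latency_encoder_ms: float
    latency_fusion_ms: float
    latency_head_ms: float

    @property
    def latency_ms(self) -> float:
        return (
            self.latency_encoder_ms
            + self.latency_fusion_ms
            + self.latency_head_ms
        )


class StreamState:
    """Bounded-memory online inference state for one video stream."""

    def __init__(self, bundle: ModelBundle, queue_size: int | None = None):
        self.bundle = bundle
        self.queue_size = queue_size or receptive_field(bundle.tcn.config)
        self.window = bundle.head.config.window
        self.queue: deque[np.ndarray] = deque(maxlen=self.queue_size)
        self.m_queue: deque[np.ndarray] = deque(maxlen=self.window)
        self.t = -1
        self.latency_log: list[FramePrediction] = []

    def __len__(self) -> int:
        return len(self.queue)


def init_stream(bundle: ModelBundle, queue_size: int | None = None) -> StreamState:
    """Fresh stream state: empty queue, frame counter at -1.

    Raises if the bundle's module dimensions are mutually inconsistent
    (checked by :class:`ModelBundle` construction as well).
    """
    return StreamState(bundle, queue_size)


def push_frame(
    state: StreamState, frame: np.ndarray
) -> tuple[StreamState, FramePrediction]:
    """Consume one H x W x 3 frame and return the updated state + prediction."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) frame, got shape {frame.shape}")
    state.t += 1

    t0 = time.perf_counter()
    e, _ = state.bundle.encoder.forward_backbone(frame[None])
    e = e[0]
    t1 = time.perf_counter()

    state.queue.append(e)
    E_queue = np.stack(state.queue)  # (<=R, d)
    m_t = state.bundle.tcn.forward(E_queue)[-1]
    state.m_queue.append(m_t)
    t2 = time.perf_counter()

    e_hat = state.bundle.head.red_W.value @ e + state.bundle.head.red_b.value
    _, p = attend(e_hat, np.stack(state.m_queue), state.bundle.head)
    label = predict_phase(p)
    t3 = time.perf_counter()

    pred = FramePrediction(
        frame_index=state.t,
        probs=p.p,
        label=label,
        latency_encoder_ms=(t1 - t0) * 1e3,
        latency_fusion_ms=(t2 - t1) * 1e3,
        latency_head_ms=(t3 - t2) * 1e3,
    )
    state.latency_log.append(pred)
    return state, pred


def stream_video(video: VideoStream, bundle: ModelBundle) -> PredictionTrack:
    """Push every frame of a video through a fresh stream."""
    state = init_stream(bundle)
    probs = np.empty((len(video), 4))
    labels = np.empty(len(video), dtype=np.int64)
    lat = np.empty(len(video))
    for t in range(len(video)):
        _, pred = push_frame(state, video.frames[t])
        probs[t] = pred.probs
        labels[t] = int(pred.label)
        lat[t] = pred.latency_ms
    return PredictionTrack(video.case_id, video.fps, probs, labels, lat)


def offline_predict(video: VideoStream, bundle: ModelBundle) -> PredictionTrack:
    """Batch causal inference over a full video (oracle for streaming)."""
    E = embed(video, bundle.encoder).values
    M = bundle.tcn.forward(E)
    probs = bundle.head.probabilities(E, M)
    labels = np.argmax(probs, axis=1)
    return PredictionTrack(video.case_id, video.fps, probs, labels)


def predict_from_embeddings(
    spatial: SpatialEmbeddingSeq, bundle: ModelBundle
) -> PredictionTrack:
    """Causal inference when spatial embeddings are already available."""
    M = bundle.tcn.forward(spatial.values)
    probs = bundle.head.probabilities(spatial.values, M)
    return PredictionTrack(
        spatial.case_id, 1.0, probs, np.argmax(probs, axis=1)
    )


def latency_summary(state: StreamState) -> dict[str, float]:
    """Median and IQR of per-stage latencies over the pushes so far (ms)."""
    if not state.latency_log:
        return {}
    out = {}
    for name in ("encoder", "fusion", "head"):
        vals = np.array(
            [getattr(p, f"latency_{name}_ms") for p in state.latency_log]
        )
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[f"{name}_median_ms"] = float(med)
        out[f"{name}_iqr_ms"] = float(q3 - q1)
    total = np.array([p.latency_ms for p in state.latency_log])
    out["total_median_ms"] = float(np.median(total))
    return out


def overlay_label(frame: np.ndarray, label: Phase) -> np.ndarray:
    """Mark the running phase in the frame's top-left corner (color patch).

    A text-free overlay: a small solid patch in the phase's reference color,
    mirroring the live display convention of showing the ongoing phase
    without occluding the surgical scene.
    """
    from .synthetic import _DEFAULT_COLORS

    out = frame.copy()
    h = max(4, frame.shape[0] // 10)
    w = max(4, frame.shape[1] // 6)
    out[:h, :w] = np.array(_DEFAULT_COLORS[int(label)], dtype=np.uint8)
    return out
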