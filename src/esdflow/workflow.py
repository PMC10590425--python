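"""Phase vocabulary and annotation data model for ESD workflow recognition.

Endoscopic submucosal dissection (ESD) procedures are annotated frame-by-frame
with exactly one of four surgical phases:

* ``Marking`` — electrocautery dots placed circumferentially around the lesion;
* ``Injection`` — submucosal fluid lift with a needle injector;
* ``Dissection`` — mucosal incision and submucosal dissection (including brief
  knife hemostasis and transient through-knife saline injection);
* ``Idle`` — instrument exchange or endoscope adjustment.

The integer coding ``Marking=0, Injection=1, Dissection=2, Idle=3`` is part of
the public contract: inter-rater agreement is a Pearson correlation on the
integer-coded sequences, which depends on the coding.

Frames are indexed 0-based; phase segments are half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np


class Phase(enum.IntEnum):
    """The four ESD workflow phases, in canonical coding order."""

    MARKING = 0
    INJECTION = 1
    DISSECTION = 2
    IDLE = 3

    @classmethod
    def from_name(cls, name: str) -> "Phase":
        try:
            return _NAME_TO_PHASE[name.strip().lower()]
        except KeyError:
            raise ValueError(
                f"unknown phase {name!r}; expected one of "
                f"{[p.display_name for p in cls]}"
            ) from None

    @property
    def display_name(self) -> str:
        return self.name.capitalize()


_NAME_TO_PHASE = {p.name.lower(): p for p in Phase}

#: Number of phases (fixed).
NUM_PHASES = 4

PHASE_NAMES = tuple(p.display_name for p in Phase)


@dataclass
class CaseMetadata:
    """Per-case clinical metadata attached to an annotation track."""

    case_id: str = ""
    date: str | None = None
    surgeon_id: str | None = None
    organ: str | None = None
    lesion_size_cm: float | None = None
    #: degree of mentor guidance in a training session
    training_status: str | None = None

    def __post_init__(self) -> None:
        if self.lesion_size_cm is not None and not self.lesion_size_cm > 0:
            raise ValueError("lesion_size_cm must be positive when present")
        if self.training_status is not None and self.training_status not in (
            "independent",
            "with help",
            "take over",
        ):
            raise ValueError(f"invalid training_status {self.training_status!r}")


@dataclass
class AnnotationTrack:
    """Frame-wise phase labels for one case at a known frame rate.

    ``labels`` is an integer array of phase codes, one entry per frame,
    frame index ``t = 0 .. T-1``.
    """

    case_id: str
    fps: float
    labels: np.ndarray
    metadata: CaseMetadata = field(default_factory=CaseMetadata)

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D sequence of phase codes")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= NUM_PHASES
        ):
            raise ValueError("labels contain codes outside 0..3")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    def phases(self) -> list[Phase]:
        return [Phase(c) for c in self.labels]


@dataclass
class VideoStream:
    """An ordered sequence of H x W x 3 8-bit frames at a known frame rate."""

    frames: np.ndarray  # (T, H, W, 3) uint8
    fps: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit (uint8)")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape[1:])  # type: ignore[return-value]


@dataclass(frozen=True)
class PhaseSegment:
    """A maximal run of one phase over the half-open frame range [start, end)."""

    start: int
    end: int
    phase: Phase

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment requires start < end")

    @property
    def num_frames(self) -> int:
        return self.end - self.start


@dataclass
class PredictionTrack:
    """Per-frame 4-way phase probabilities with hard labels and latencies."""

    case_id: str
    fps: float
    probs: np.ndarray  # (T, 4)
    labels: np.ndarray  # (T,)
    latency_ms: np.ndarray | None = None  # (T,) total per-frame latency

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.probs.ndim != 2 or self.probs.shape[1] != NUM_PHASES:
            raise ValueError("probs must have shape (T, 4)")
        if self.labels.shape != (self.probs.shape[0],):
            raise ValueError("labels must align with probs rows")

    def __len__(self) -> int:
        return int(self.labels.size)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def segments_from_labels(track: AnnotationTrack) -> list[PhaseSegment]:
    """Run-length encode a track into contiguous, phase-alternating segments.

    Concatenating the returned segments reproduces ``track.labels`` exactly;
    adjacent segments always differ in phase.
    """
    labels = track.labels
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [
        PhaseSegment(int(s), int(e), Phase(int(labels[s])))
        for s, e in zip(starts, ends)
    ]


def labels_from_segments(
    segments: Iterable[PhaseSegment | tuple[int, int, Phase]],
) -> np.ndarray:
    """Expand half-open segments into a contiguous frame-wise label array.

    Segments must tile ``[0, T)`` with no gap or overlap.
    """
    out: list[np.ndarray] = []
    cursor = 0
    for seg in segments:
        if isinstance(seg, tuple):
            seg = PhaseSegment(*seg)
        if seg.start != cursor:
            raise ValueError(
                f"segment starting at {seg.start} does not follow frame {cursor} "
                "(gap or overlap)"
            )
        out.append(np.full(seg.num_frames, int(seg.phase), dtype=np.int64))
        cursor = seg.end
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out)


def downsample_track(track: AnnotationTrack, target_fps: float) -> AnnotationTrack:
    """Reduce a track's frame rate by keeping the first frame of each window.

    ``track.fps`` must be an integer multiple of ``target_fps`` (the annotation
    protocol downsamples e.g. 25 fps video to 1 fps).
    """
    if target_fps > track.fps:
        raise ValueError("target_fps must not exceed track fps")
    ratio = track.fps / target_fps
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fps ratio {track.fps}/{target_fps} = {ratio} is not an integer"
        )
    step = int(round(ratio))
    return replace(track, fps=target_fps, labels=track.labels[::step].copy())


def pearson_agreement(a: AnnotationTrack, b: AnnotationTrack) -> float:
    """Inter-rater agreement: Pearson correlation of integer-coded labels.

    Both tracks must have the same length (>= 2 frames) and at least one must
    be non-constant; the value depends on the canonical phase coding.
    """
    if len(a) != len(b):
        raise ValueError(f"track lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 frames for a correlation")
    xa = a.labels.astype(np.float64)
    xb = b.labels.astype(np.float64)
    sa = xa.std()
    sb = xb.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined: a track is constant")
    r = float(np.corrcoef(xa, xb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def validate_track(track: AnnotationTrack) -> None:
    """Raise if a track violates the annotation protocol invariants."""
    # dataclass __post_init__ already enforces label codes and fps; this hook
    # re-checks after in-place mutation of .labels
    AnnotationTrack(track.case_id, track.fps, track.labels, track.metadata)


def paired_lengths_consistent(video: VideoStream, track: AnnotationTrack) -> bool:
    """True when a video and an annotation track describe the same frames."""
    return len(video) == len(track) and video.fps == track.fps
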