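"""File I/O for annotations, case metadata, predictions and frame videos.

Two plain-text annotation dialects are supported:

* frame CSV — header ``frame,phase``; one row per frame, 0-based, contiguous;
* segment CSV — header ``start,end,phase``; half-open frame ranges tiling
  ``[0, T)``.

Prediction CSVs use the streaming engine's column layout
``frame,p_marking,p_injection,p_dissection,p_idle,label,latency_ms``.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .workflow import (
    AnnotationTrack,
    CaseMetadata,
    Phase,
    PredictionTrack,
    VideoStream,
    labels_from_segments,
    segments_from_labels,
)

_FRAME_COLS = ["frame", "phase"]
_SEGMENT_COLS = ["start", "end", "phase"]


class AnnotationFormatError(ValueError):
    """A malformed annotation file (unknown phase, gap/overlap, bad header)."""


def _parse_phase(raw: object, row: int) -> Phase:
    try:
        return Phase.from_name(str(raw))
    except ValueError as exc:
        raise AnnotationFormatError(f"row {row}: {exc}") from None


def parse_annotation_file(
    path: str | Path, fps: float, case_id: str | None = None
) -> AnnotationTrack:
    """Read a frame or segment CSV into an :class:`AnnotationTrack`.

    The dialect is detected from the header. Frame indices must be 0-based and
    contiguous; segment ranges must tile ``[0, T)`` exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if case_id is None:
        case_id = path.stem
    if cols == _FRAME_COLS:
        frames = df["frame"].astype(int).to_numpy()
        expected = np.arange(len(frames))
        if not np.array_equal(frames, expected):
            bad = int(np.flatnonzero(frames != expected[: len(frames)])[0])
            raise AnnotationFormatError(
                f"row {bad}: frame indices must be 0-based and contiguous "
                f"(got {frames[bad]}, expected {bad})"
            )
        labels = np.array(
            [int(_parse_phase(p, i)) for i, p in enumerate(df["phase"])],
            dtype=np.int64,
        )
        return AnnotationTrack(case_id, fps, labels)
    if cols == _SEGMENT_COLS:
        segs = [
            (int(r.start), int(r.end), _parse_phase(r.phase, i))
            for i, r in enumerate(df.itertuples(index=False))
        ]
        try:
            labels = labels_from_segments(segs)
        except ValueError as exc:
            raise AnnotationFormatError(str(exc)) from None
        return AnnotationTrack(case_id, fps, labels)
    raise AnnotationFormatError(
        f"unrecognized header {list(df.columns)}; expected {_FRAME_COLS} or "
        f"{_SEGMENT_COLS}"
    )


def write_annotation_file(
    track: AnnotationTrack, path: str | Path, dialect: str = "frame"
) -> None:
    """Write a track as a frame or segment CSV (round-trips exactly)."""
    path = Path(path)
    if dialect == "frame":
        df = pd.DataFrame(
            {
                "frame": np.arange(len(track)),
                "phase": [Phase(c).display_name for c in track.labels],
            }
        )
    elif dialect == "segment":
        segs = segments_from_labels(track)
        df = pd.DataFrame(
            {
                "start": [s.start for s in segs],
                "end": [s.end for s in segs],
                "phase": [s.phase.display_name for s in segs],
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False)


def read_case_metadata(path: str | Path) -> tuple[CaseMetadata, float | None]:
    """Read per-case metadata JSON; returns (metadata, fps-if-recorded)."""
    with open(path) as fh:
        raw = json.load(fh)
    fps = raw.pop("fps", None)
    meta = CaseMetadata(
        case_id=raw.get("case_id", ""),
        date=raw.get("date"),
        surgeon_id=raw.get("surgeon_id"),
        organ=raw.get("organ"),
        lesion_size_cm=raw.get("lesion_size_cm"),
        training_status=raw.get("training_status"),
    )
    return meta, fps


def write_case_metadata(
    meta: CaseMetadata, fps: float | None, path: str | Path
) -> None:
    data = asdict(meta)
    if fps is not None:
        data["fps"] = fps
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# Video frames
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)")


def write_frame_dir(video: VideoStream, directory: str | Path) -> None:
    """Dump a video as zero-padded PNG frames (frame_000000.png, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(len(video)):
        iio.imwrite(directory / f"frame_{t:06d}.png", video.frames[t])


def read_frame_dir(
    directory: str | Path, fps: float, case_id: str | None = None
) -> VideoStream:
    """Read a directory of numbered PNG frames into a :class:`VideoStream`."""
    directory = Path(directory)
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() == ".png"),
        key=lambda p: int(_FRAME_RE.findall(p.stem)[-1]),
    )
    if not files:
        raise FileNotFoundError(f"no PNG frames found in {directory}")
    frames = np.stack([iio.imread(p) for p in files])
    if frames.ndim == 4 and frames.shape[-1] == 4:  # strip alpha if present
        frames = frames[..., :3]
    return VideoStream(frames.astype(np.uint8), fps, case_id or directory.name)


def read_video_file(path: str | Path, fps: float | None = None) -> VideoStream:
    """Read a standard video container via imageio."""
    path = Path(path)
    frames = np.stack(list(iio.imiter(path)))
    if fps is None:
        meta = iio.immeta(path)
        fps = float(meta.get("fps", 25.0))
    return VideoStream(frames[..., :3].astype(np.uint8), fps, path.stem)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

_PRED_COLS = [
    "frame",
    "p_marking",
    "p_injection",
    "p_dissection",
    "p_idle",
    "label",
    "latency_ms",
]


def write_prediction_csv(pred: PredictionTrack, path: str | Path) -> None:
    lat = (
        pred.latency_ms
        if pred.latency_ms is not None
        else np.full(len(pred), np.nan)
    )
    df = pd.DataFrame(
        {
            "frame": np.arange(len(pred)),
            "p_marking": pred.probs[:, 0],
            "p_injection": pred.probs[:, 1],
            "p_dissection": pred.probs[:, 2],
            "p_idle": pred.probs[:, 3],
            "label": [Phase(c).display_name for c in pred.labels],
            "latency_ms": lat,
        }
    )
    df.to_csv(path, index=False)


def read_prediction_csv(
    path: str | Path, fps: float = 1.0, case_id: str | None = None
) -> PredictionTrack:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != _PRED_COLS:
        raise ValueError(f"unrecognized prediction CSV header {list(df.columns)}")
    probs = df[["p_marking", "p_injection", "p_dissection", "p_idle"]].to_numpy()
    labels = np.array([int(Phase.from_name(s)) for s in df["label"]])
    lat = df["latency_ms"].to_numpy()
    if np.isnan(lat).all():
        lat = None
    return PredictionTrack(case_id or path.stem, fps, probs, labels, lat)
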