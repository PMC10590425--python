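"""Skill analytics from phase tracks and the structured summary report.

The central skill score is the **Normalized Transition index (NT-index)**:
the cumulative count of phase transitions divided by the lesion size in cm.
Hesitant operation shows up as frequent changes between Dissection and Idle,
so a lower NT-index curve indicates a smoother, more skilled procedure.
Lesion size normalizes away the longer duration of larger lesions.

The summary report collects basic case information, the phase color bar,
phase-duration statistics (pie data), the transition matrix, the NT-index
curve and derived skill ratios (Idle period / tumor size, Idle period /
Dissection period, procedure duration / tumor size) into a JSON-serializable
document with a self-contained HTML rendering.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from string import Template

import numpy as np

from .workflow import (
    AnnotationTrack,
    CaseMetadata,
    NUM_PHASES,
    PHASE_NAMES,
    Phase,
    PredictionTrack,
    segments_from_labels,
)

_PHASE_HEX = ("#be4646", "#465ac8", "#d2aa50", "#50a05a")


@dataclass
class TransitionStats:
    """Total transition count and the 4x4 from->to transition matrix."""

    total_transitions: int
    matrix: np.ndarray  # (4, 4) ints, zero diagonal

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)


def count_transitions(labels: np.ndarray | AnnotationTrack) -> TransitionStats:
    """Count frame-to-frame phase changes and accumulate the matrix."""
    x = labels.labels if isinstance(labels, AnnotationTrack) else np.asarray(labels)
    mat = np.zeros((NUM_PHASES, NUM_PHASES), dtype=np.int64)
    if x.size >= 2:
        prev, nxt = x[:-1], x[1:]
        change = prev != nxt
        np.add.at(mat, (prev[change], nxt[change]), 1)
    return TransitionStats(int(mat.sum()), mat)


@dataclass
class NTCurve:
    """NT-index over time: cumulative transitions / lesion size (per cm)."""

    times_s: np.ndarray
    values: np.ndarray
    per_minute: bool = False

    @property
    def final_value(self) -> float:
        return float(self.values[-1]) if self.values.size else 0.0


def nt_index_curve(
    labels: np.ndarray | AnnotationTrack,
    fps: float,
    lesion_size_cm: float,
    per_minute: bool = False,
) -> NTCurve:
    """Cumulative-transition curve normalized by lesion size.

    ``per_minute=True`` additionally divides by elapsed minutes, turning the
    score into a transition *rate*; the default is the cumulative reading.
    """
    if not lesion_size_cm > 0:
        raise ValueError("lesion_size_cm must be positive")
    x = labels.labels if isinstance(labels, AnnotationTrack) else np.asarray(labels)
    T = x.size
    times = np.arange(T) / fps
    if T == 0:
        return NTCurve(times, np.empty(0), per_minute)
    changes = np.concatenate(([0], (x[1:] != x[:-1]).astype(np.int64)))
    cum = np.cumsum(changes)
    values = cum / lesion_size_cm
    if per_minute:
        minutes = np.maximum(times / 60.0, 1.0 / (60.0 * fps))
        values = values / minutes
    return NTCurve(times, values.astype(np.float64), per_minute)


def phase_periods(
    labels: np.ndarray | AnnotationTrack, fps: float
) -> dict[Phase, tuple[float, float]]:
    """Per-phase (duration_s, ratio-of-total); ratios sum to 1."""
    x = labels.labels if isinstance(labels, AnnotationTrack) else np.asarray(labels)
    if x.size == 0:
        raise ValueError("empty label sequence")
    counts = np.bincount(x, minlength=NUM_PHASES)
    return {
        Phase(k): (counts[k] / fps, counts[k] / x.size) for k in range(NUM_PHASES)
    }


def derived_scores(
    periods: dict[Phase, tuple[float, float]],
    lesion_size_cm: float,
    total_duration_s: float,
) -> dict[str, float | None]:
    """The three offline skill ratios.

    ``idle_per_dissection`` is ``None`` (unavailable) when the dissection
    duration is zero.
    """
    if not lesion_size_cm > 0:
        raise ValueError("lesion_size_cm must be positive")
    idle_s = periods[Phase.IDLE][0]
    diss_s = periods[Phase.DISSECTION][0]
    return {
        "idle_per_tumor_s_per_cm": idle_s / lesion_size_cm,
        "idle_per_dissection": (idle_s / diss_s) if diss_s > 0 else None,
        "procedure_per_tumor_s_per_cm": total_duration_s / lesion_size_cm,
    }


@dataclass
class SkillSummary:
    """Numbers feeding the skill section of the report."""

    phase_durations_s: dict[str, float]
    phase_ratios: dict[str, float]
    final_nt_index: float | None
    idle_per_tumor_s_per_cm: float | None
    idle_per_dissection: float | None
    procedure_per_tumor_s_per_cm: float | None
    training_status: str | None = None


@dataclass
class ReportDocument:
    """Losslessly serializable structured summary of one procedure."""

    basic_info: dict[str, object]
    color_bar: list[dict[str, object]]  # segment list: start, end, phase
    duration_pie: dict[str, float]  # phase -> ratio
    transition_total: int
    transition_matrix: list[list[int]]
    nt_times_s: list[float]
    nt_values: list[float]
    skill: SkillSummary
    source: str = "predictions"  # labels came from the model or the annotator

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ReportDocument":
        d = dict(d)
        d["skill"] = SkillSummary(**d["skill"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ReportDocument":
        return cls.from_dict(json.loads(s))


def generate_report(
    meta: CaseMetadata,
    predictions: PredictionTrack | AnnotationTrack,
    lesion_size_cm: float | None = None,
    hospital: str = "",
    training_session: str = "",
    source: str | None = None,
) -> ReportDocument:
    """Assemble the structured summary report from a phase track.

    Works from model predictions or ground-truth annotations (recorded in
    ``source``). A missing lesion size leaves the NT-index and per-tumor
    scores unavailable; the report is still produced.
    """
    if len(predictions) == 0:
        raise ValueError("cannot report on an empty prediction track")
    labels = predictions.labels
    fps = predictions.fps
    if source is None:
        source = (
            "predictions" if isinstance(predictions, PredictionTrack)
            else "annotations"
        )
    if lesion_size_cm is None:
        lesion_size_cm = meta.lesion_size_cm
    track = AnnotationTrack("report", fps, labels)
    segs = segments_from_labels(track)
    periods = phase_periods(labels, fps)
    trans = count_transitions(labels)
    total_s = labels.size / fps
    if lesion_size_cm is not None:
        nt = nt_index_curve(labels, fps, lesion_size_cm)
        scores = derived_scores(periods, lesion_size_cm, total_s)
        final_nt = nt.final_value
        nt_times = nt.times_s.tolist()
        nt_values = nt.values.tolist()
    else:
        scores = {
            "idle_per_tumor_s_per_cm": None,
            "idle_per_dissection": (
                periods[Phase.IDLE][0] / periods[Phase.DISSECTION][0]
                if periods[Phase.DISSECTION][0] > 0
                else None
            ),
            "procedure_per_tumor_s_per_cm": None,
        }
        final_nt, nt_times, nt_values = None, [], []
    skill = SkillSummary(
        phase_durations_s={p.display_name: periods[p][0] for p in Phase},
        phase_ratios={p.display_name: periods[p][1] for p in Phase},
        final_nt_index=final_nt,
        idle_per_tumor_s_per_cm=scores["idle_per_tumor_s_per_cm"],
        idle_per_dissection=scores["idle_per_dissection"],
        procedure_per_tumor_s_per_cm=scores["procedure_per_tumor_s_per_cm"],
        training_status=meta.training_status,
    )
    return ReportDocument(
        basic_info={
            "date": meta.date,
            "hospital": hospital,
            "case_id": meta.case_id,
            "endoscopist": meta.surgeon_id,
            "organ": meta.organ,
            "lesion_size_cm": lesion_size_cm,
            "training_session": training_session,
            "duration_s": total_s,
        },
        color_bar=[
            {"start": s.start, "end": s.end, "phase": s.phase.display_name}
            for s in segs
        ],
        duration_pie={p.display_name: periods[p][1] for p in Phase},
        transition_total=trans.total_transitions,
        transition_matrix=trans.matrix.tolist(),
        nt_times_s=nt_times,
        nt_values=nt_values,
        skill=skill,
        source=source,
    )


def rank_by_nt_index(reports: list[ReportDocument]) -> list[ReportDocument]:
    """Order procedures by final NT-index, ascending (smoother first)."""
    return sorted(
        reports,
        key=lambda r: (
            r.skill.final_nt_index if r.skill.final_nt_index is not None
            else np.inf
        ),
    )


# ---------------------------------------------------------------------------
# HTML rendering
# ---------------------------------------------------------------------------

_HTML_TEMPLATE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Procedure summary — $case_id</title>
<style>
 body { font-family: sans-serif; margin: 2em; max-width: 60em; }
 h2 { border-bottom: 1px solid #999; }
 table { border-collapse: collapse; } td, th { border: 1px solid #bbb;
 padding: 0.3em 0.6em; } .bar { display: flex; height: 2em; }
</style></head><body>
<h1>Surgical workflow summary report</h1>
<h2 id="basic-info">Basic information</h2>
<table>$basic_rows</table>
<h2 id="phase-color-bar">Phase color bar</h2>
<div class="bar">$bar_divs</div>
<p>$legend</p>
<h2 id="duration-pie">Phase duration distribution</h2>
$pie_img
<table><tr><th>Phase</th><th>Duration (s)</th><th>Ratio</th></tr>$pie_rows</table>
<h2 id="transition-matrix">Phase transitions</h2>
<p>Total transitions: <b>$total_transitions</b></p>
<table>$trans_rows</table>
<h2 id="nt-curve">NT-index curve</h2>
$nt_img
<p>Final NT-index: <b>$final_nt</b> (transitions per cm of lesion)</p>
<h2 id="skill-summary">Skill summary</h2>
<table>$skill_rows</table>
<p>Training status: $training_status &mdash; phase source: $source</p>
</body></html>
"""
)


def _fig_to_data_uri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=80, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def render_html(doc: ReportDocument, embed_figures: bool = True) -> str:
    """Self-contained HTML rendering containing every report section."""
    info = doc.basic_info
    basic_rows = "".join(
        f"<tr><th>{k}</th><td>{v if v is not None else '—'}</td></tr>"
        for k, v in info.items()
    )
    total = max(seg["end"] for seg in doc.color_bar) if doc.color_bar else 1
    bar_divs = "".join(
        '<div style="width:{:.2f}%;background:{}" title="{}"></div>'.format(
            100.0 * (seg["end"] - seg["start"]) / total,
            _PHASE_HEX[Phase.from_name(seg["phase"])],
            seg["phase"],
        )
        for seg in doc.color_bar
    )
    legend = " ".join(
        f'<span style="color:{_PHASE_HEX[i]}">&#9632; {PHASE_NAMES[i]}</span>'
        for i in range(NUM_PHASES)
    )
    pie_rows = "".join(
        "<tr><td>{}</td><td>{:.1f}</td><td>{:.1%}</td></tr>".format(
            name, doc.skill.phase_durations_s[name], ratio
        )
        for name, ratio in doc.duration_pie.items()
    )
    header = "<tr><th>from \\ to</th>" + "".join(
        f"<th>{n}</th>" for n in PHASE_NAMES
    ) + "</tr>"
    trans_rows = header + "".join(
        f"<tr><th>{PHASE_NAMES[i]}</th>"
        + "".join(f"<td>{doc.transition_matrix[i][j]}</td>"
                  for j in range(NUM_PHASES))
        + "</tr>"
        for i in range(NUM_PHASES)
    )
    skill_pairs = [
        ("Final NT-index (/cm)", doc.skill.final_nt_index),
        ("Idle period / tumor size (s/cm)", doc.skill.idle_per_tumor_s_per_cm),
        ("Idle period / Dissection period", doc.skill.idle_per_dissection),
        ("Procedure duration / tumor size (s/cm)",
         doc.skill.procedure_per_tumor_s_per_cm),
    ]
    skill_rows = "".join(
        "<tr><th>{}</th><td>{}</td></tr>".format(
            k, f"{v:.3f}" if v is not None else "not available"
        )
        for k, v in skill_pairs
    )
    pie_img = nt_img = ""
    if embed_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ratios = [doc.duration_pie[n] for n in PHASE_NAMES]
        if sum(r > 0 for r in ratios):
            fig, ax = plt.subplots(figsize=(3.2, 3.2))
            keep = [i for i, r in enumerate(ratios) if r > 0]
            ax.pie(
                [ratios[i] for i in keep],
                labels=[PHASE_NAMES[i] for i in keep],
                colors=[_PHASE_HEX[i] for i in keep],
                autopct="%1.0f%%",
            )
            pie_img = f'<img alt="duration pie" src="{_fig_to_data_uri(fig)}">'
        if doc.nt_values:
            fig, ax = plt.subplots(figsize=(4.5, 2.5))
            ax.step(doc.nt_times_s, doc.nt_values, where="post")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("NT-index (/cm)")
            nt_img = f'<img alt="NT-index curve" src="{_fig_to_data_uri(fig)}">'
    return _HTML_TEMPLATE.substitute(
        case_id=info.get("case_id", ""),
        basic_rows=basic_rows,
        bar_divs=bar_divs,
        legend=legend,
        pie_img=pie_img,
        pie_rows=pie_rows,
        total_transitions=doc.transition_total,
        trans_rows=trans_rows,
        nt_img=nt_img,
        final_nt=(
            f"{doc.skill.final_nt_index:.2f}"
            if doc.skill.final_nt_index is not None
            else "not available"
        ),
        skill_rows=skill_rows,
        training_status=doc.skill.training_status or "—",
        source=doc.source,
    )


def write_report(
    doc: ReportDocument, directory: str | Path, stem: str = "report"
) -> tuple[Path, Path]:
    """Write report.json + report.html; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    jpath = directory / f"{stem}.json"
    hpath = directory / f"{stem}.html"
    jpath.write_text(doc.to_json(indent=2))
    hpath.write_text(render_html(doc))
    return jpath, hpath
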