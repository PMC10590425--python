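"""Synthetic phase-structured ESD-like video for end-to-end testing.

Real ESD recordings cannot be redistributed, so this module generates the
whole study material programmatically:

* a **semi-Markov workflow grammar** draws phase segments with explicit dwell
  times — Marking first, then Injection/Dissection alternation interleaved
  with Idle, mirroring the clinical order of the annotation protocol;
* a **skill profile** scales the rate of transitions into Idle and the dwell
  times, so "novice" traces hesitate more than "expert" ones (the mechanism
  behind the NT-index skill score);
* an **appearance model** renders one frame per label: a phase-specific base
  color, sinusoidal texture, an optional moving tool-like highlight and
  Gaussian pixel noise — enough structure for a frame encoder to learn from,
  with none of the anatomy of real endoscopy;
* a **simulated second rater** perturbs segment boundaries and relabels
  segments to emulate inter-annotator disagreement.

Everything is deterministic given its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .workflow import (
    AnnotationTrack,
    CaseMetadata,
    NUM_PHASES,
    Phase,
    VideoStream,
    segments_from_labels,
)

# Default dwell means (seconds). Dissection dominates total procedure time,
# as it does clinically; these are fixture choices for desk-scale testing.
_DEFAULT_DWELL_MEAN_S = {
    Phase.MARKING: 20.0,
    Phase.INJECTION: 10.0,
    Phase.DISSECTION: 60.0,
    Phase.IDLE: 8.0,
}

# Transition weights encode the protocol's clinical order: Marking happens
# once at the start; afterwards Injection and Dissection alternate with Idle
# interleaved (no path back to Marking).
_DEFAULT_TRANSITIONS: dict[Phase, dict[Phase, float]] = {
    Phase.MARKING: {Phase.IDLE: 0.5, Phase.INJECTION: 0.5},
    Phase.INJECTION: {Phase.DISSECTION: 0.8, Phase.IDLE: 0.2},
    Phase.DISSECTION: {Phase.IDLE: 0.6, Phase.INJECTION: 0.4},
    Phase.IDLE: {Phase.INJECTION: 0.4, Phase.DISSECTION: 0.6},
}


@dataclass
class WorkflowGrammar:
    """Semi-Markov grammar over the four phases (zero self-transitions)."""

    initial_phase: Phase = Phase.MARKING
    transitions: dict[Phase, dict[Phase, float]] = field(
        default_factory=lambda: {
            p: dict(w) for p, w in _DEFAULT_TRANSITIONS.items()
        }
    )
    dwell_mean_s: dict[Phase, float] = field(
        default_factory=lambda: dict(_DEFAULT_DWELL_MEAN_S)
    )
    #: gamma shape of dwell distributions (mean/shape = scale); higher = less
    #: dispersed segment lengths
    dwell_shape: float = 4.0
    #: mean seconds until a hesitation pause interrupts a working phase at
    #: unit skill multiplier (exponential hazard; Idle itself is never
    #: interrupted)
    interrupt_mean_s: float = 150.0

    def __post_init__(self) -> None:
        for p, out in self.transitions.items():
            if p in out and out[p] != 0:
                raise ValueError(f"self-transition weight on {p} must be zero")
            if any(w < 0 for w in out.values()):
                raise ValueError("transition weights must be nonnegative")
        for p, m in self.dwell_mean_s.items():
            if not m > 0:
                raise ValueError(f"dwell mean for {p} must be positive")


@dataclass
class SkillProfile:
    """Operator skill knobs: both multipliers must be positive.

    ``idle_rate_multiplier`` scales transition weights *into* Idle — hesitant
    operators exchange tools and pause more often. ``dwell_scale`` stretches
    all dwell times.
    """

    idle_rate_multiplier: float = 1.0
    dwell_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.idle_rate_multiplier > 0 and self.dwell_scale > 0):
            raise ValueError("skill multipliers must be positive")


EXPERT = SkillProfile(idle_rate_multiplier=1.0, dwell_scale=1.0)
NOVICE = SkillProfile(idle_rate_multiplier=3.0, dwell_scale=1.0)

# Per-phase base colors (RGB, 8-bit), pairwise distinct.
_DEFAULT_COLORS = (
    (190, 70, 70),  # Marking  — reddish
    (70, 90, 200),  # Injection — blue lift
    (210, 170, 80),  # Dissection — yellow submucosa
    (80, 160, 90),  # Idle — green drape
)


@dataclass
class AppearanceConfig:
    """Rendering parameters for synthetic frames."""

    height: int = 64
    width: int = 64
    base_colors: tuple[tuple[int, int, int], ...] = _DEFAULT_COLORS
    texture_amplitude: float = 18.0
    noise_sd: float = 8.0
    tool_overlay: bool = True

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame size must be positive")
        if len(set(self.base_colors)) != NUM_PHASES:
            raise ValueError("per-phase base colors must be pairwise distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def sample_phase_sequence(
    grammar: WorkflowGrammar,
    duration_s: float,
    skill: SkillProfile = EXPERT,
    fps: float = 1.0,
    seed: int = 0,
    case_id: str = "synthetic",
) -> AnnotationTrack:
    """Draw a phase-labeled track from the semi-Markov grammar.

    Starts in ``grammar.initial_phase``, samples a gamma dwell (mean scaled by
    ``skill.dwell_scale``), then the next phase from the transition weights
    with weights into Idle multiplied by ``skill.idle_rate_multiplier``;
    truncates at ``duration_s``. Hesitation is modeled as an exponential
    interruption hazard on working (non-Idle) phases whose rate also scales
    with the idle multiplier: an interrupted dwell is cut short and the
    operator drops into Idle. Deterministic given ``seed``.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    total_frames = int(round(duration_s * fps))
    labels = np.empty(total_frames, dtype=np.int64)
    t = 0
    phase = grammar.initial_phase
    while t < total_frames:
        mean = grammar.dwell_mean_s[phase] * skill.dwell_scale
        dwell_s = rng.gamma(grammar.dwell_shape, mean / grammar.dwell_shape)
        interrupted = False
        if phase != Phase.IDLE and grammar.interrupt_mean_s > 0:
            pause_s = rng.exponential(
                grammar.interrupt_mean_s / skill.idle_rate_multiplier
            )
            if pause_s < dwell_s:
                dwell_s = pause_s
                interrupted = True
        n = max(1, int(round(dwell_s * fps)))
        n = min(n, total_frames - t)
        labels[t : t + n] = int(phase)
        t += n
        if interrupted:
            phase = Phase.IDLE
        else:
            phase = _next_phase(grammar, phase, skill, rng)
    return AnnotationTrack(case_id, fps, labels)


def _next_phase(
    grammar: WorkflowGrammar,
    phase: Phase,
    skill: SkillProfile,
    rng: np.random.Generator,
) -> Phase:
    out = grammar.transitions.get(phase, {})
    cands = [p for p, w in out.items() if w > 0 and p != phase]
    if not cands:
        raise ValueError(f"grammar deadlock: phase {phase} has no outgoing weight")
    weights = np.array(
        [
            out[p] * (skill.idle_rate_multiplier if p == Phase.IDLE else 1.0)
            for p in cands
        ]
    )
    weights = weights / weights.sum()
    return cands[int(rng.choice(len(cands), p=weights))]


def render_video(
    track: AnnotationTrack,
    appearance: AppearanceConfig | None = None,
    seed: int = 0,
) -> VideoStream:
    """Render one frame per label; pure function of (track, appearance, seed)."""
    app = appearance or AppearanceConfig()
    rng = np.random.default_rng(seed)
    h, w = app.height, app.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((len(track), h, w, 3), dtype=np.uint8)
    colors = np.asarray(app.base_colors, dtype=np.float64)
    for t, code in enumerate(track.labels):
        base = colors[code][None, None, :]
        # phase-dependent spatial frequency makes texture informative too
        freq = 0.15 + 0.1 * code
        tex = app.texture_amplitude * np.sin(freq * xx + 0.7 * freq * yy)
        img = base + tex[..., None]
        if app.tool_overlay:
            cx = w * (0.5 + 0.35 * np.sin(0.12 * t + code))
            cy = h * (0.5 + 0.35 * np.cos(0.09 * t))
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img = img + 70.0 * np.exp(-r2 / (2.0 * (0.06 * w) ** 2))[..., None]
        if app.noise_sd > 0:
            img = img + rng.normal(0.0, app.noise_sd, size=(h, w, 3))
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
    return VideoStream(frames, track.fps, track.case_id)


def simulate_rater(
    track: AnnotationTrack,
    boundary_jitter_s: float = 1.0,
    relabel_rate: float = 0.0,
    seed: int = 0,
) -> AnnotationTrack:
    """Emulate an independent annotator.

    Each interior segment boundary is shifted by ``round(N(0, jitter*fps))``
    frames (clipped so every segment stays nonempty), then each segment is
    relabeled to a uniformly random *other* phase with probability
    ``relabel_rate``.
    """
    if not 0 <= relabel_rate <= 1:
        raise ValueError("relabel_rate must lie in [0, 1]")
    if boundary_jitter_s < 0:
        raise ValueError("boundary_jitter_s must be nonnegative")
    rng = np.random.default_rng(seed)
    segs = segments_from_labels(track)
    if not segs:
        return AnnotationTrack(track.case_id, track.fps, track.labels.copy(),
                               track.metadata)
    bounds = [s.start for s in segs] + [len(track)]
    sd = boundary_jitter_s * track.fps
    for i in range(1, len(bounds) - 1):
        if sd > 0:
            shift = int(round(rng.normal(0.0, sd)))
        else:
            shift = 0
        lo, hi = bounds[i - 1] + 1, bounds[i + 1] - 1
        bounds[i] = int(np.clip(bounds[i] + shift, lo, hi))
    labels = np.empty(len(track), dtype=np.int64)
    for i, seg in enumerate(segs):
        phase = int(seg.phase)
        if relabel_rate > 0 and rng.random() < relabel_rate:
            others = [p for p in range(NUM_PHASES) if p != phase]
            phase = int(others[rng.integers(len(others))])
        labels[bounds[i] : bounds[i + 1]] = phase
    return AnnotationTrack(track.case_id, track.fps, labels, track.metadata)


@dataclass
class SyntheticCase:
    """One rendered synthetic case: video + ground-truth track + metadata."""

    video: VideoStream
    track: AnnotationTrack


def make_dataset(
    n_cases: int,
    duration_s: float = 600.0,
    fps: float = 1.0,
    skill: SkillProfile = EXPERT,
    appearance: AppearanceConfig | None = None,
    grammar: WorkflowGrammar | None = None,
    seed: int = 0,
    lesion_size_cm: float = 2.0,
    surgeon_id: str = "synthetic-surgeon",
) -> list[SyntheticCase]:
    """Generate ``n_cases`` date-ordered synthetic cases (one seed stream).

    Case dates are consecutive days, so the chronological cross-validation
    split is well defined on the result.
    """
    grammar = grammar or WorkflowGrammar()
    root = np.random.SeedSequence(seed)
    cases = []
    for i, child in enumerate(root.spawn(n_cases)):
        s1, s2 = child.generate_state(2, dtype=np.uint64) >> np.uint64(33)
        track = sample_phase_sequence(
            grammar, duration_s, skill, fps, int(s1), case_id=f"case{i:03d}"
        )
        track.metadata = CaseMetadata(
            case_id=track.case_id,
            date=f"2024-01-{i + 1:02d}" if i < 28 else f"2024-02-{i - 27:02d}",
            surgeon_id=surgeon_id,
            organ=("rectum", "stomach", "esophagus")[i % 3],
            lesion_size_cm=lesion_size_cm,
        )
        video = render_video(track, appearance, int(s2))
        cases.append(SyntheticCase(video, track))
    return cases
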