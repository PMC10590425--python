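"""Generate a synthetic ESD-like case and exercise the annotation tooling.

Draws a phase-labeled procedure from the semi-Markov workflow grammar,
renders its video, writes/reads both annotation CSV dialects, and measures
inter-rater agreement against a simulated second annotator.
"""

import tempfile
from pathlib import Path

import esdflow as ef

track = ef.sample_phase_sequence(
    ef.WorkflowGrammar(), duration_s=600, fps=1.0, seed=1, case_id="demo"
)
video = ef.render_video(track, ef.AppearanceConfig(height=64, width=64), seed=2)
segments = ef.segments_from_labels(track)

print(f"case '{track.case_id}': {len(track)} frames at {track.fps} fps, "
      f"{len(segments)} phase segments")
for phase, (dur, ratio) in ef.phase_periods(track.labels, track.fps).items():
    print(f"  {phase.display_name:<11} {dur:6.0f} s  ({ratio:5.1%} of procedure)")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "annotations.csv"
    ef.write_annotation_file(track, path, dialect="segment")
    back = ef.parse_annotation_file(path, fps=1.0, case_id="demo")
    print("segment-CSV round trip exact:", (back.labels == track.labels).all())

# a second annotator with 1 s boundary jitter and 2% segment relabeling
rater2 = ef.simulate_rater(track, boundary_jitter_s=1.0, relabel_rate=0.02,
                           seed=3)
pcc = ef.pearson_agreement(track, rater2)
print(f"inter-rater Pearson agreement: {pcc:.3f} "
      "(Pearson correlation of the integer-coded label sequences; "
      "1.0 = identical labels)")
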