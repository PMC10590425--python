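"""Skill analytics: transitions, NT-index, phase periods, report round-trip."""

import numpy as np
import pytest

import esdflow as ef
from esdflow.skill import (
    count_transitions,
    derived_scores,
    generate_report,
    nt_index_curve,
    phase_periods,
    rank_by_nt_index,
    render_html,
    ReportDocument,
)
from esdflow.synthetic import NOVICE, EXPERT, WorkflowGrammar, sample_phase_sequence
from esdflow.workflow import (
    AnnotationTrack,
    CaseMetadata,
    Phase,
    PredictionTrack,
    segments_from_labels,
)


class TestTransitions:
    def test_constant_sequence_has_none(self):
        stats = count_transitions(np.full(10, 2))
        assert stats.total_transitions == 0 and (stats.matrix == 0).all()

    def test_direct_count_example(self):
        stats = count_transitions(np.array([0, 3, 0, 3]))
        assert stats.total_transitions == 3
        assert stats.matrix[0, 3] == 2 and stats.matrix[3, 0] == 1

    def test_total_equals_segments_minus_one(self, rng):
        for _ in range(50):
            labels = rng.integers(0, 4, size=int(rng.integers(1, 80)))
            track = AnnotationTrack("x", 1.0, labels)
            stats = count_transitions(labels)
            assert stats.total_transitions == len(segments_from_labels(track)) - 1
            assert np.trace(stats.matrix) == 0


class TestNTIndex:
    def test_no_transitions_gives_zero_curve(self):
        curve = nt_index_curve(np.zeros(20, dtype=int), 1.0, 2.0)
        assert (curve.values == 0).all()

    def test_final_value_direct_division(self):
        labels = np.array([0, 1, 0, 1, 0, 1])  # 5 transitions
        curve = nt_index_curve(labels, 1.0, 2.0)
        assert curve.final_value == pytest.approx(2.5)

    def test_curve_nondecreasing_step_function(self, rng):
        labels = rng.integers(0, 4, size=60)
        curve = nt_index_curve(labels, 1.0, 1.5)
        assert (np.diff(curve.values) >= 0).all()
        assert curve.values[0] == 0.0

    def test_final_times_lesion_equals_transition_count_exactly(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 4, size=int(rng.integers(2, 100)))
            size = float(rng.uniform(0.5, 5.0))
            curve = nt_index_curve(labels, 1.0, size)
            assert curve.final_value * size == pytest.approx(
                count_transitions(labels).total_transitions, abs=1e-9
            )

    def test_nonpositive_lesion_rejected(self):
        with pytest.raises(ValueError, match="lesion"):
            nt_index_curve(np.zeros(5, dtype=int), 1.0, 0.0)

    def test_per_minute_mode_divides_by_elapsed_time(self):
        labels = np.array([0, 1] * 30)
        cum = nt_index_curve(labels, 1.0, 1.0)
        rate = nt_index_curve(labels, 1.0, 1.0, per_minute=True)
        t = 59
        assert rate.values[t] == pytest.approx(cum.values[t] / (t / 60.0))


class TestPhasePeriods:
    def test_single_phase_track(self):
        periods = phase_periods(np.full(30, int(Phase.DISSECTION)), 1.0)
        assert periods[Phase.DISSECTION] == (30.0, 1.0)
        assert periods[Phase.IDLE] == (0.0, 0.0)

    def test_mixed_track_durations_and_ratios(self):
        labels = np.concatenate([np.full(30, 2), np.full(20, 3), np.full(10, 1)])
        periods = phase_periods(labels, 1.0)
        assert periods[Phase.DISSECTION][0] == pytest.approx(30.0)
        assert periods[Phase.IDLE][0] == pytest.approx(20.0)
        assert periods[Phase.INJECTION][1] == pytest.approx(10 / 60)
        assert sum(r for _, r in periods.values()) == pytest.approx(1.0)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            phase_periods(np.empty(0, dtype=int), 1.0)


class TestDerivedScores:
    def test_hand_arithmetic(self):
        labels = np.concatenate([np.full(20, 3), np.full(30, 2), np.full(10, 0)])
        periods = phase_periods(labels, 1.0)
        scores = derived_scores(periods, 2.0, 60.0)
        assert scores["idle_per_tumor_s_per_cm"] == pytest.approx(10.0)
        assert scores["idle_per_dissection"] == pytest.approx(2 / 3)
        assert scores["procedure_per_tumor_s_per_cm"] == pytest.approx(30.0)

    def test_zero_idle(self):
        periods = phase_periods(np.full(40, 2), 1.0)
        scores = derived_scores(periods, 2.0, 40.0)
        assert scores["idle_per_tumor_s_per_cm"] == 0.0
        assert scores["idle_per_dissection"] == 0.0

    def test_zero_dissection_marked_unavailable(self):
        periods = phase_periods(np.full(40, 3), 1.0)
        scores = derived_scores(periods, 2.0, 40.0)
        assert scores["idle_per_dissection"] is None


class TestReport:
    @pytest.fixture()
    def sample_doc(self):
        track = sample_phase_sequence(WorkflowGrammar(), 200, seed=31)
        meta = CaseMetadata("caseX", "2024-03-01", "trainee-1", "stomach",
                            2.0, "with help")
        pred = PredictionTrack(
            "caseX", 1.0,
            np.eye(4)[track.labels], track.labels,
        )
        return generate_report(meta, pred, hospital="Synthetic General")

    def test_json_round_trip_is_lossless(self, sample_doc):
        back = ReportDocument.from_json(sample_doc.to_json())
        assert back == sample_doc

    def test_color_bar_matches_segments(self, sample_doc):
        labels = np.concatenate([
            np.full(seg["end"] - seg["start"],
                    int(Phase.from_name(seg["phase"])))
            for seg in sample_doc.color_bar
        ])
        trans = count_transitions(labels)
        assert trans.total_transitions == sample_doc.transition_total

    def test_html_contains_every_section(self, sample_doc):
        html = render_html(sample_doc, embed_figures=False)
        for anchor in ("basic-info", "phase-color-bar", "duration-pie",
                       "transition-matrix", "nt-curve", "skill-summary"):
            assert f'id="{anchor}"' in html
        assert "with help" in html

    def test_missing_lesion_size_keeps_report_producible(self):
        track = sample_phase_sequence(WorkflowGrammar(), 100, seed=5)
        meta = CaseMetadata("caseY")
        pred = PredictionTrack("caseY", 1.0, np.eye(4)[track.labels],
                               track.labels)
        doc = generate_report(meta, pred)
        assert doc.skill.final_nt_index is None
        assert doc.skill.idle_per_tumor_s_per_cm is None
        html = render_html(doc, embed_figures=False)
        assert "not available" in html

    def test_write_report_files(self, sample_doc, tmp_path):
        from esdflow.skill import write_report

        jpath, hpath = write_report(sample_doc, tmp_path)
        assert jpath.exists() and hpath.exists()
        assert ReportDocument.from_json(jpath.read_text()) == sample_doc


class TestSkillSeparation:
    def test_novice_profile_raises_final_nt_index(self):
        """Higher idle-rate multiplier -> more transitions (50-seed majority)."""
        wins = 0
        for seed in range(50):
            te = sample_phase_sequence(WorkflowGrammar(), 400, EXPERT, seed=seed)
            tn = sample_phase_sequence(WorkflowGrammar(), 400, NOVICE, seed=seed)
            nte = nt_index_curve(te.labels, 1.0, 2.0).final_value
            ntn = nt_index_curve(tn.labels, 1.0, 2.0).final_value
            wins += ntn > nte
        assert wins > 25

    def test_ranking_orders_by_final_nt(self):
        docs = []
        for i, labels in enumerate([[0, 1] * 20, [0] * 40, [0, 1, 2, 3] * 10]):
            meta = CaseMetadata(f"c{i}", lesion_size_cm=2.0)
            pred = PredictionTrack(f"c{i}", 1.0,
                                   np.eye(4)[np.asarray(labels)],
                                   np.asarray(labels))
            docs.append(generate_report(meta, pred))
        ranked = rank_by_nt_index(docs)
        nts = [d.skill.final_nt_index for d in ranked]
        assert nts == sorted(nts)
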