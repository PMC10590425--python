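"""Evaluation statistics for phase recognition.

Frame-level metrics follow the standard multi-class / one-vs-rest scheme:

* overall accuracy = trace of the 4x4 confusion matrix / total frames;
* macro precision and recall over the phases present in the ground truth
  (a phase with zero predicted positives contributes precision 0);
* per-phase ROC / AUROC over the phase's predicted probability, with the
  Youden index J = sensitivity + specificity - 1 selecting the operating
  threshold, at which the hatted counts TP̂ / TN̂ / FP̂ / FN̂ give

      specificity = TN̂/(TN̂+FP̂),  sensitivity = TP̂/(TP̂+FN̂),
      orderliness = (TP̂+TN̂)/(TP̂+TN̂+FP̂+FN̂);

* group aggregates are per-case means with Student-t 95% confidence
  intervals, and groups are compared with a two-sided paired t-test.

AUROC by trapezoidal integration of the ROC curve equals the Mann-Whitney
U statistic formulation with ties counted 1/2 — the test suite asserts the
equivalence to 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .workflow import AnnotationTrack, NUM_PHASES, Phase, PredictionTrack


# ---------------------------------------------------------------------------
# Confusion-based overall metrics
# ---------------------------------------------------------------------------


def confusion_matrix(
    pred: PredictionTrack | np.ndarray, truth: AnnotationTrack | np.ndarray
) -> np.ndarray:
    """4x4 counts; rows = true phase, columns = predicted phase."""
    p = pred.labels if isinstance(pred, PredictionTrack) else np.asarray(pred)
    t = truth.labels if isinstance(truth, AnnotationTrack) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return _sk_confusion(t, p, labels=np.arange(NUM_PHASES))


def overall_metrics(
    cm: np.ndarray, average: str = "macro"
) -> tuple[float, float, float]:
    """(accuracy, precision, recall) from a 4x4 confusion matrix.

    Macro averaging (default) runs over phases present in the truth; micro
    averaging pools the one-vs-rest counts.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    accuracy = float(tp.sum() / total)
    present = cm.sum(axis=1) > 0
    if average == "macro":
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        precision = float(prec[present].mean())
        recall = float(rec[present].mean())
    elif average == "micro":
        precision = float(tp.sum() / (tp.sum() + fp[present].sum()))
        recall = float(tp.sum() / (tp.sum() + fn.sum()))
    else:
        raise ValueError(f"unknown average {average!r}")
    return accuracy, precision, recall


# ---------------------------------------------------------------------------
# ROC / AUROC / Youden
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """One-vs-rest ROC curve with trapezoidal AUROC."""

    thresholds: np.ndarray  # decreasing
    fpr: np.ndarray  # nondecreasing, starts at 0 ends at 1
    tpr: np.ndarray
    auroc: float
    scores: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    truth: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def roc_auroc(scores: np.ndarray, truth: np.ndarray) -> RocCurve:
    """ROC by threshold sweep over the scores of one phase (one-vs-rest).

    ``truth`` is binary. Requires both classes present. All-tied scores give
    AUROC exactly 0.5 (Mann-Whitney tie convention).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(int)
    if truth.min() == truth.max():
        raise ValueError("ROC undefined: only one class present in truth")
    fpr, tpr, thr = _sk_roc_curve(truth, scores, drop_intermediate=False)
    return RocCurve(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)),
                    scores, truth)


def auroc_mann_whitney(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUROC (ties get half credit); oracle twin of trapezoids."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = stats.rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def youden_threshold(curve: RocCurve) -> tuple[float, float]:
    """(threshold, J) maximizing J = sensitivity + specificity - 1.

    Ties break toward the higher threshold (more conservative positive calls);
    sklearn's threshold array is decreasing, so the first maximum wins.
    """
    j = curve.tpr - curve.fpr
    # tolerance absorbs one-ulp differences between algebraically tied J
    # values (e.g. 2/3 vs 1 - 1/3); first index = highest threshold
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    thr = float(curve.thresholds[best])
    if np.isinf(thr):  # the sentinel point above the largest score
        thr = float(np.max(curve.scores)) + 1.0
    return thr, float(j[best])


@dataclass
class PhaseMetrics:
    """Per-phase operating-point metrics at the Youden threshold."""

    phase: Phase
    auroc: float
    youden_threshold: float
    specificity: float
    sensitivity: float
    orderliness: float
    tp: int
    tn: int
    fp: int
    fn: int
    available: bool = True


def phase_metrics(
    probs: PredictionTrack | np.ndarray,
    truth: AnnotationTrack | np.ndarray,
    phase: Phase,
) -> PhaseMetrics:
    """AUROC + Youden-thresholded specificity/sensitivity/orderliness.

    When the phase is absent from the truth (or universal), the metrics are
    marked unavailable rather than raising — matching the reporting
    convention for cases without e.g. a Marking phase.
    """
    p = probs.probs[:, int(phase)] if isinstance(probs, PredictionTrack) else (
        np.asarray(probs, dtype=np.float64)
    )
    t = truth.labels if isinstance(truth, AnnotationTrack) else np.asarray(truth)
    y = (t == int(phase)).astype(int)  # one-vs-rest on multi-class labels
    if y.min() == y.max():
        return PhaseMetrics(phase, np.nan, np.nan, np.nan, np.nan, np.nan,
                            0, 0, 0, 0, available=False)
    curve = roc_auroc(p, y)
    thr, _ = youden_threshold(curve)
    pred_pos = p >= thr
    tp = int(np.sum(pred_pos & (y == 1)))
    tn = int(np.sum(~pred_pos & (y == 0)))
    fp = int(np.sum(pred_pos & (y == 0)))
    fn = int(np.sum(~pred_pos & (y == 1)))
    return PhaseMetrics(
        phase=phase,
        auroc=curve.auroc,
        youden_threshold=thr,
        specificity=tn / (tn + fp),
        sensitivity=tp / (tp + fn),
        orderliness=(tp + tn) / (tp + tn + fp + fn),
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def t_confidence_interval(
    values: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Student-t confidence interval for the mean of per-case metrics."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        raise ValueError("confidence interval requires n >= 2 cases")
    mean = values.mean()
    sd = values.std(ddof=1)
    tq = stats.t.ppf(0.5 + level / 2, df=n - 1)
    half = tq * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def paired_t_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value between matched per-case metrics."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal-length samples")
    if a.size < 2:
        raise ValueError("paired test requires n >= 2")
    if np.var(a - b, ddof=1) == 0:
        raise ValueError("degenerate: zero variance of the paired differences")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class CaseMetricRow:
    case_id: str
    accuracy: float
    precision: float
    recall: float
    phase_metrics: dict[Phase, PhaseMetrics]


def evaluate_cases(
    predictions: list[PredictionTrack], truths: list[AnnotationTrack]
) -> dict:
    """Per-case metric table plus pooled confusion / per-phase AUROC.

    Aggregates are per-case means with 95% t-CIs (cases, not frames, are the
    replication unit); pooled AUROCs concatenate frames from all cases.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must pair up")
    rows: list[CaseMetricRow] = []
    pooled_cm = np.zeros((NUM_PHASES, NUM_PHASES), dtype=np.int64)
    all_probs: list[np.ndarray] = []
    all_truth: list[np.ndarray] = []
    for pred, truth in zip(predictions, truths):
        cm = confusion_matrix(pred, truth)
        pooled_cm += cm
        acc, prec, rec = overall_metrics(cm)
        pm = {
            ph: phase_metrics(pred.probs[:, int(ph)], truth.labels, ph)
            for ph in Phase
        }
        rows.append(CaseMetricRow(pred.case_id, acc, prec, rec, pm))
        all_probs.append(pred.probs)
        all_truth.append(truth.labels)
    probs_cat = np.concatenate(all_probs, axis=0)
    truth_cat = np.concatenate(all_truth)
    pooled_phase = {}
    for ph in Phase:
        y = (truth_cat == int(ph)).astype(int)
        pooled_phase[ph] = (
            phase_metrics(probs_cat[:, int(ph)], truth_cat, ph)
            if 0 < y.sum() < y.size
            else PhaseMetrics(ph, np.nan, np.nan, np.nan, np.nan, np.nan,
                              0, 0, 0, 0, available=False)
        )
    accs = np.array([r.accuracy for r in rows])
    summary = {
        "accuracy_mean": float(accs.mean()),
        "accuracy_ci": t_confidence_interval(accs) if accs.size >= 2 else None,
        "pooled_accuracy": overall_metrics(pooled_cm)[0],
    }
    return {
        "cases": rows,
        "pooled_confusion": pooled_cm,
        "pooled_phase_metrics": pooled_phase,
        "summary": summary,
    }
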