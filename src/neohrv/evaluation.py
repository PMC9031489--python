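"""Epoch-based and event-based detection metrics.

Epoch metrics come from the confusion matrix (sensitivity, specificity,
precision, F1, all in %) and the ROC area, computed per patient and over
the pooled ("concatenated") epochs of the whole cohort.  Event metrics
score expert-annotated seizure events: the good detection rate (events
with at least one predicted-positive epoch inside them), the false
discovery rate of predicted events, false detections per hour and the
detection delay from expert onset to the end of the first detecting
epoch.  Predicted events are maximal runs of consecutive
predicted-positive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted, truth) -> ConfusionCounts:
    """Count the four outcome categories of aligned boolean label vectors
    (True = seizure)."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum(predicted & truth)),
        fp=int(np.sum(predicted & ~truth)),
        tn=int(np.sum(~predicted & ~truth)),
        fn=int(np.sum(~predicted & truth)),
    )


def epoch_metrics(counts: ConfusionCounts) -> dict:
    """SEN, SPE, PRE and F1 in percent; a metric whose denominator is zero
    is missing (NaN)."""
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    sen = ratio(counts.tp, counts.tp + counts.fn)
    spe = ratio(counts.tn, counts.tn + counts.fp)
    pre = ratio(counts.tp, counts.tp + counts.fp)
    if np.isfinite(sen) and np.isfinite(pre) and (sen + pre) > 0:
        f1 = 2.0 * sen * pre / (sen + pre)
    else:
        f1 = np.nan
    return {"SEN": sen, "SPE": spe, "PRE": pre, "F1": f1}


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve via the rank statistic
    P(score+ > score-) + P(tie)/2; NaN when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def concatenated_auc(folds) -> float:
    """AUC over the pooled per-epoch scores of every patient (controls
    included); order-invariant by construction."""
    scores = np.concatenate([f.scores for f in folds])
    truth = np.concatenate([f.truth for f in folds])
    return roc_auc(scores, truth)


# ---------------------------------------------------------------------------
# event-based metrics
# ---------------------------------------------------------------------------

def predicted_events(predicted, epoch_bounds) -> list:
    """Merge maximal runs of consecutive predicted-positive epochs into
    predicted event intervals; a single negative epoch splits runs."""
    predicted = np.asarray(predicted, dtype=bool)
    bounds = list(epoch_bounds)
    if len(bounds) != predicted.size:
        raise ValueError("predictions and epoch bounds differ in length")
    events = []
    start = None
    for flag, (s, e) in zip(predicted, bounds):
        if flag and start is None:
            start, end = s, e
        elif flag:
            end = e
        elif start is not None:
            events.append((start, end))
            start = None
    if start is not None:
        events.append((start, end))
    return events


def _overlaps(a, b) -> bool:
    return min(a[1], b[1]) > max(a[0], b[0])


def detection_delay(event, predicted, epoch_bounds) -> float:
    """Seconds from the expert onset to the end of the earliest
    predicted-positive epoch overlapping the event; NaN if undetected."""
    predicted = np.asarray(predicted, dtype=bool)
    for flag, (s, e) in zip(predicted, epoch_bounds):
        if flag and _overlaps(event, (s, e)):
            return float(e - event[0])
    return np.nan


def event_metrics(expert_events, predicted, epoch_bounds, record_hours=None) -> dict:
    """GDR, FDR and FDH for one record.

    GDR (%) counts expert events containing at least one predicted-positive
    epoch.  A predicted event (merged run of positive epochs) is false when
    it overlaps no expert event; FDR (%) is the share of false predicted
    events among all predicted events (missing when nothing is predicted)
    and FDH their number per analyzed hour.  GDR is missing for event-free
    (control) records, which still contribute to FDR/FDH.
    """
    predicted = np.asarray(predicted, dtype=bool)
    bounds = list(epoch_bounds)
    if record_hours is None:
        record_hours = sum(e - s for s, e in bounds) / 3600.0
    detected = []
    delays = []
    for ev in expert_events:
        d = detection_delay(ev, predicted, bounds)
        detected.append(np.isfinite(d))
        delays.append(d)
    pred_events = predicted_events(predicted, bounds)
    false_events = [pe for pe in pred_events
                    if not any(_overlaps(pe, ev) for ev in expert_events)]
    gdr = 100.0 * np.mean(detected) if expert_events else np.nan
    if pred_events:
        fdr = 100.0 * len(false_events) / len(pred_events)
        fdh = len(false_events) / record_hours if record_hours > 0 else np.nan
    else:
        fdr = np.nan
        fdh = 0.0
    return {
        "GDR": gdr,
        "FDR": fdr,
        "FDH": fdh,
        "delays_s": delays,
        "detected": detected,
        "n_predicted_events": len(pred_events),
        "n_false_events": len(false_events),
    }


# ---------------------------------------------------------------------------
# per-patient summaries
# ---------------------------------------------------------------------------

def summarize_folds(folds, annotations_by_patient) -> pd.DataFrame:
    """Per-patient epoch and event metrics for a set of LOSO folds.

    ``annotations_by_patient`` maps patient id to its AnnotationSet (or an
    event list).  Returns one row per patient.
    """
    rows = []
    for f in folds:
        events = annotations_by_patient.get(f.patient_id, [])
        events = getattr(events, "events", events)
        bounds = list(zip(f.epoch_start_s, f.epoch_end_s))
        counts = confusion(f.predicted, f.truth)
        row = {"patient_id": f.patient_id, "group": f.group,
               "AUC": roc_auc(f.scores, f.truth),
               **epoch_metrics(counts)}
        em = event_metrics(events, f.predicted, bounds)
        delays = [d for d in em["delays_s"] if np.isfinite(d)]
        row.update({"GDR": em["GDR"], "FDR": em["FDR"], "FDH": em["FDH"],
                    "TimeDelay": float(np.mean(delays)) if delays else np.nan,
                    "TP": counts.tp, "FP": counts.fp,
                    "TN": counts.tn, "FN": counts.fn})
        rows.append(row)
    return pd.DataFrame(rows)


def mean_se(values) -> tuple:
    """Mean and standard error over the finite entries."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan
    se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return float(v.mean()), float(se)


def cohort_summary(per_patient: pd.DataFrame, pathological_only=True) -> dict:
    """Mean ± standard error of every metric across pathological patients
    (the reporting convention for LOSO seizure-detection results); FDH and
    FDR also include controls via the pooled rows when requested."""
    metrics = ("AUC", "SEN", "SPE", "GDR", "FDH", "FDR", "F1", "TimeDelay")
    rows = per_patient[per_patient["group"] != "CP"] if pathological_only else per_patient
    out = {}
    for m in metrics:
        mean, se = mean_se(rows[m])
        out[m] = {"mean": mean, "se": se}
    return out
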