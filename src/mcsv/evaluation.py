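"""Alarm generation, SPH/SOP scoring, metrics and validation protocols.

Alarm semantics: an alarm raised at time ``t`` predicts a seizure no sooner
than the seizure prediction horizon (SPH) and no later than SPH plus the
seizure occurrence period (SOP).  It is a true positive if some onset falls
in ``[t + SPH, t + SPH + SOP]``; an alarm whose onset lands inside the SPH,
or that matches no onset at all, is a false positive; a seizure with no
matching alarm is a false negative.  Each onset is credited to at most one
alarm (greedy in time).

Two granularities are reported side by side: event-level TP/FP/FN drive
sensitivity and the false-prediction rate per inter-ictal hour, while
window-level predicted labels drive accuracy and AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .preprocessing import SegmentGrid
from .record import EEGRecord, SeizureAnnotation

__all__ = [
    "AlarmEvent",
    "ScoringConfig",
    "AlarmScore",
    "label_windows",
    "alarms_from_probs",
    "score_alarms",
    "compute_metrics",
    "auc",
    "split_holdout",
    "loso_cv",
    "cross_subject_cv",
]

IIL, PIL, EXCLUDED = 0, 1, 2


@dataclass(frozen=True)
class AlarmEvent:
    """An alarm raised at ``time`` seconds (end of the triggering window)."""

    time: float


@dataclass
class ScoringConfig:
    """SPH/SOP alarm semantics and trigger rule.

    An alarm fires at the end of the ``persistence``-th consecutive window
    whose pre-ictal probability exceeds ``threshold``; further alarms are
    suppressed for ``refractory_s`` seconds (defaults to the SOP).
    """

    sph_minutes: float = 5.0
    sop_minutes: float = 10.0
    threshold: float = 0.5
    persistence: int = 1
    refractory_s: float | None = None

    def __post_init__(self) -> None:
        if self.sph_minutes < 0 or self.sop_minutes <= 0:
            raise ValueError("SPH must be >= 0 and SOP > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def sph_s(self) -> float:
        return self.sph_minutes * 60.0

    @property
    def sop_s(self) -> float:
        return self.sop_minutes * 60.0

    @property
    def refractory(self) -> float:
        return self.sop_s if self.refractory_s is None else self.refractory_s


@dataclass
class AlarmScore:
    """Event-level counts plus window-level metrics."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    window_tp: int = 0
    window_fp: int = 0
    window_fn: int = 0
    window_tn: int = 0
    interictal_hours: float = 0.0
    sensitivity: float = math.nan
    accuracy: float = math.nan
    fpr_per_hour: float = math.nan
    auc: float = math.nan
    undefined: list[str] = field(default_factory=list)


def label_windows(
    record: EEGRecord,
    grid: SegmentGrid,
    pil_minutes: float = 5.0,
) -> np.ndarray:
    """Per-segment labels: 1 pre-ictal, 0 inter-ictal, 2 excluded (ictal).

    A segment is pre-ictal if its span intersects ``[onset - pil, onset)``
    for any annotated onset; segments overlapping an ictal span are
    excluded.  Without annotations everything is inter-ictal (warned).
    """
    labels = np.zeros(grid.k, dtype=np.int8)
    if not record.annotations:
        warnings.warn("record has no annotations: all windows labeled inter-ictal", stacklevel=2)
        return labels
    pil_s = pil_minutes * 60.0
    for i in range(grid.k):
        t0, t1 = grid.span(i)
        for a in record.annotations:
            if t0 < a.offset and t1 > a.onset:  # overlaps ictal
                labels[i] = EXCLUDED
                break
            p0 = max(a.onset - pil_s, 0.0)
            if t0 < a.onset and t1 > p0:
                labels[i] = PIL
    return labels


def alarms_from_probs(
    probs: np.ndarray,
    end_times: np.ndarray,
    config: ScoringConfig,
) -> list[AlarmEvent]:
    """Persistence-and-refractory alarm trigger over window probabilities."""
    alarms: list[AlarmEvent] = []
    run = 0
    suppressed_until = -math.inf
    for p, t in zip(probs, end_times):
        if t < suppressed_until:
            run = 0
            continue
        run = run + 1 if p > config.threshold else 0
        if run >= config.persistence:
            alarms.append(AlarmEvent(float(t)))
            suppressed_until = t + config.refractory
            run = 0
    return alarms


def score_alarms(
    alarms: list[AlarmEvent],
    annotations: list[SeizureAnnotation],
    config: ScoringConfig,
) -> tuple[int, int, int]:
    """Event-level (TP, FP, FN) under SPH/SOP semantics.

    Greedy in time: each alarm claims the earliest unclaimed onset inside
    its ``[t + SPH, t + SPH + SOP]`` window.
    """
    onsets = sorted(a.onset for a in annotations)
    claimed = [False] * len(onsets)
    tp = fp = 0
    for alarm in sorted(alarms, key=lambda a: a.time):
        lo, hi = alarm.time + config.sph_s, alarm.time + config.sph_s + config.sop_s
        hit = next(
            (i for i, o in enumerate(onsets) if not claimed[i] and lo <= o <= hi), None
        )
        if hit is None:
            fp += 1
        else:
            claimed[hit] = True
            tp += 1
    fn = claimed.count(False)
    return tp, fp, fn


def interictal_hours(
    record_duration: float,
    annotations: list[SeizureAnnotation],
    alarms: list[AlarmEvent],
    config: ScoringConfig,
    pil_minutes: float = 5.0,
) -> float:
    """Inter-ictal time: record minus ictal, pre-ictal and post-alarm spans.

    The SPH+SOP span following each alarm is excluded so a false alarm is
    normalised by the time in which a new alarm could actually have fired.
    """
    spans = []
    for a in annotations:
        spans.append((max(a.onset - pil_minutes * 60.0, 0.0), min(a.offset, record_duration)))
    for al in alarms:
        spans.append((al.time, min(al.time + config.sph_s + config.sop_s, record_duration)))
    # merge overlapping spans
    spans.sort()
    merged: list[list[float]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    covered = sum(hi - lo for lo, hi in merged)
    return max(record_duration - covered, 0.0) / 3600.0


def compute_metrics(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    interictal_hours: float,
) -> AlarmScore:
    """Sensitivity TP/(TP+FN), accuracy (TP+TN)/total, FPR FP/hours.

    Metrics with a zero denominator are set to NaN and listed in
    ``undefined`` rather than silently reported as 0.
    """
    score = AlarmScore(tp=tp, fp=fp, fn=fn, tn=tn, interictal_hours=interictal_hours)
    if tp + fn > 0:
        score.sensitivity = tp / (tp + fn)
    else:
        score.undefined.append("sensitivity")
    total = tp + fp + fn + tn
    if total > 0:
        score.accuracy = (tp + tn) / total
    else:
        score.undefined.append("accuracy")
    if interictal_hours > 0:
        score.fpr_per_hour = fp / interictal_hours
    else:
        score.undefined.append("fpr_per_hour")
    return score


def auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of the pre-ictal probability."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, probs))


def split_holdout(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified window-level train/test index split (train ``fraction``)."""
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=y
    )
    for name, part in (("train", train_idx), ("test", test_idx)):
        if len(np.unique(np.asarray(y)[part])) < 2:
            warnings.warn(f"{name} split lost a class (n too small)", stacklevel=2)
    return np.sort(train_idx), np.sort(test_idx)


def loso_cv(seizure_ids: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-seizure-out folds over per-window seizure/record ids.

    Returns (train_idx, test_idx) pairs, one per distinct id; the held-out
    seizure's windows never appear in its training fold.
    """
    seizure_ids = np.asarray(seizure_ids)
    units = np.unique(seizure_ids)
    if len(units) < 2:
        raise ValueError("leave-one-seizure-out needs at least 2 seizures")
    return [
        (np.nonzero(seizure_ids != u)[0], np.nonzero(seizure_ids == u)[0]) for u in units
    ]


def cross_subject_cv(patient_ids: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-patient-out folds over per-window patient ids."""
    patient_ids = np.asarray(patient_ids)
    units = np.unique(patient_ids)
    if len(units) < 2:
        raise ValueError("cross-subject validation needs at least 2 patients")
    return [
        (np.nonzero(patient_ids != u)[0], np.nonzero(patient_ids == u)[0]) for u in units
    ]
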