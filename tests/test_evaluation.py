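"""Window labeling, SPH/SOP alarm scoring, metrics and CV protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcsv.evaluation import (
    AlarmEvent,
    ScoringConfig,
    alarms_from_probs,
    auc,
    compute_metrics,
    cross_subject_cv,
    interictal_hours,
    label_windows,
    loso_cv,
    score_alarms,
    split_holdout,
)
from mcsv.preprocessing import segment
from mcsv.record import EEGRecord, SeizureAnnotation

SPH_SOP = ScoringConfig(sph_minutes=5.0, sop_minutes=10.0)


def _record_with_onset(onset, duration=1400.0, offset_delta=30.0):
    return EEGRecord(
        np.zeros((1, int(250 * duration))),
        250.0,
        ["Cz"],
        annotations=[SeizureAnnotation(onset, onset + offset_delta, "seiz")],
    )


class TestLabelWindows:
    def test_preictal_span_covers_75_windows(self):
        rec = _record_with_onset(1000.0)
        labels = label_windows(rec, segment(rec, 4.0), pil_minutes=5.0)
        assert int(np.sum(labels == 1)) == 75  # [700, 1000) / 4 s
        assert labels[175] == 1 and labels[174] == 0

    def test_preictal_span_clipped_at_record_start(self):
        rec = _record_with_onset(100.0, duration=600.0)
        labels = label_windows(rec, segment(rec, 4.0), pil_minutes=5.0)
        assert int(np.sum(labels == 1)) == 25  # [0, 100)

    def test_straddling_window_counts_as_preictal(self):
        rec = _record_with_onset(1002.0)
        labels = label_windows(rec, segment(rec, 4.0), pil_minutes=5.0)
        # window [700, 704) intersects [702, 1002) -> pre-ictal
        assert labels[175] == 1

    def test_ictal_windows_excluded(self):
        rec = _record_with_onset(1000.0)
        labels = label_windows(rec, segment(rec, 4.0))
        assert np.all(labels[250:257] == 2)

    def test_no_annotations_warns_all_interictal(self):
        rec = EEGRecord(np.zeros((1, 250 * 60)), 250.0, ["Cz"])
        with pytest.warns(UserWarning, match="no annotations"):
            labels = label_windows(rec, segment(rec, 4.0))
        assert np.all(labels == 0)


class TestAlarms:
    def test_no_probability_no_alarm(self):
        cfg = ScoringConfig(threshold=0.5)
        assert alarms_from_probs(np.zeros(50), np.arange(50.0), cfg) == []

    def test_single_positive_window_fires_at_its_end_time(self):
        cfg = ScoringConfig(threshold=0.5, persistence=1)
        probs = np.zeros(10)
        probs[4] = 0.9
        alarms = alarms_from_probs(probs, 4.0 * np.arange(1, 11), cfg)
        assert alarms == [AlarmEvent(20.0)]

    def test_persistence_requires_consecutive_positives(self):
        cfg = ScoringConfig(threshold=0.5, persistence=3)
        probs = np.array([0.9, 0.9, 0.1, 0.9, 0.9, 0.0])
        assert alarms_from_probs(probs, np.arange(6.0), cfg) == []

    def test_refractory_suppresses_follow_up_alarms(self):
        cfg = ScoringConfig(threshold=0.5, persistence=1, refractory_s=100.0)
        probs = np.ones(50) * 0.9
        alarms = alarms_from_probs(probs, 4.0 * np.arange(1, 51), cfg)
        # suppression spans [4, 104); the window ending exactly at 104 may fire
        assert [a.time for a in alarms] == [4.0, 104.0]


class TestScoreAlarms:
    def test_alarm_inside_lead_window_is_true_positive(self):
        anns = [SeizureAnnotation(1000.0, 1030.0)]
        tp, fp, fn = score_alarms([AlarmEvent(500.0)], anns, SPH_SOP)
        assert (tp, fp, fn) == (1, 0, 0)  # onset in [800, 1400]

    def test_alarm_inside_sph_is_false_positive_and_seizure_missed(self):
        anns = [SeizureAnnotation(1000.0, 1030.0)]
        tp, fp, fn = score_alarms([AlarmEvent(950.0)], anns, SPH_SOP)
        assert (tp, fp, fn) == (0, 1, 1)

    def test_unalarmed_seizure_is_false_negative(self):
        anns = [SeizureAnnotation(1000.0, 1030.0)]
        assert score_alarms([], anns, SPH_SOP) == (0, 0, 1)

    def test_each_onset_credited_to_at_most_one_alarm(self):
        anns = [SeizureAnnotation(1000.0, 1030.0)]
        alarms = [AlarmEvent(500.0), AlarmEvent(550.0)]
        tp, fp, fn = score_alarms(alarms, anns, SPH_SOP)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_scoring_invariant_to_alarm_order(self):
        anns = [SeizureAnnotation(1000.0, 1030.0), SeizureAnnotation(3000.0, 3030.0)]
        alarms = [AlarmEvent(2500.0), AlarmEvent(500.0)]
        assert score_alarms(alarms, anns, SPH_SOP) == score_alarms(alarms[::-1], anns, SPH_SOP)

    @settings(deadline=None, max_examples=50)
    @given(
        alarm_times=st.lists(st.floats(0, 5000), max_size=6),
        onsets=st.lists(st.floats(700, 5000), min_size=1, max_size=4, unique=True),
    )
    def test_tp_plus_fn_equals_seizure_count(self, alarm_times, onsets):
        anns = [SeizureAnnotation(o, o + 10.0) for o in onsets]
        alarms = [AlarmEvent(t) for t in alarm_times]
        tp, fp, fn = score_alarms(alarms, anns, SPH_SOP)
        assert tp + fn == len(onsets)
        more_tp, _, _ = score_alarms(alarms + [AlarmEvent(1.0)], anns, SPH_SOP)
        assert more_tp >= tp


class TestMetrics:
    def test_sensitivity_arithmetic(self):
        assert compute_metrics(9, 0, 1, 0, 1.0).sensitivity == pytest.approx(0.9)

    def test_fpr_per_hour_arithmetic(self):
        assert compute_metrics(0, 2, 0, 0, 10.0).fpr_per_hour == pytest.approx(0.2)

    def test_accuracy_arithmetic(self):
        assert compute_metrics(1, 1, 1, 97, 1.0).accuracy == pytest.approx(0.98)

    def test_zero_denominators_flagged_not_silently_zero(self):
        score = compute_metrics(0, 0, 0, 0, 0.0)
        assert math.isnan(score.sensitivity) and math.isnan(score.fpr_per_hour)
        assert {"sensitivity", "accuracy", "fpr_per_hour"} <= set(score.undefined)

    def test_interictal_hours_excludes_event_and_alarm_spans(self):
        cfg = ScoringConfig(sph_minutes=5.0, sop_minutes=10.0)
        anns = [SeizureAnnotation(3000.0, 3030.0)]
        hours = interictal_hours(7200.0, anns, [AlarmEvent(500.0)], cfg, pil_minutes=5.0)
        # 2 h minus PIL+ictal (330 s) minus SPH+SOP after the alarm (900 s)
        assert hours == pytest.approx((7200 - 330 - 900) / 3600)


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_complement_symmetry(self, rng):
        probs = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        assert auc(probs, labels) + auc(1 - probs, labels) == pytest.approx(1.0)

    def test_independent_scores_near_half(self, rng):
        n = 4000
        probs = rng.random(n)
        labels = (rng.random(n) < 0.5).astype(int)
        n1, n0 = labels.sum(), n - labels.sum()
        se = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc(probs, labels) - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestSplits:
    def test_holdout_sizes_and_stratification(self, rng):
        y = np.repeat([0, 1], [80, 20])
        tr, te = split_holdout(rng.normal(size=(100, 3)), y, 0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20
        assert abs(y[te].sum() - 4) <= 1

    def test_holdout_seeded_determinism(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.tile([0, 1], 25)
        assert np.array_equal(split_holdout(X, y, seed=3)[0], split_holdout(X, y, seed=3)[0])

    def test_loso_folds_cover_each_seizure_once(self):
        ids = np.array([0, 0, 1, 1, 2, 2, 2])
        folds = loso_cv(ids)
        assert len(folds) == 3
        for u, (tr, te) in enumerate(folds):
            assert set(ids[te]) == {u}
            assert u not in set(ids[tr])

    def test_cross_subject_no_patient_leakage(self):
        pids = np.repeat(np.arange(4), 5)
        folds = cross_subject_cv(pids)
        assert len(folds) == 4
        for u, (tr, te) in enumerate(folds):
            assert set(pids[te]).isdisjoint(set(pids[tr]))

    def test_insufficient_units_rejected(self):
        with pytest.raises(ValueError):
            loso_cv(np.zeros(5))
        with pytest.raises(ValueError):
            cross_subject_cv(np.ones(5))

    def test_fold_metric_averaging_is_arithmetic_mean(self):
        sens = [1.0, 0.5, 0.75]
        assert np.mean(sens) == pytest.approx(0.75)
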