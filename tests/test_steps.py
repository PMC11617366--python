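"""Step-count accuracy arithmetic and binary-SVM walking detection."""

import numpy as np
import pytest

import collarsense as cs
from collarsense.labels import BehaviorLabel
from collarsense.steps import NEGATIVE_LABEL, POSITIVE_LABEL


class StubDetector:
    """Predicts a fixed boolean pattern, cycled over the windows."""

    def __init__(self, pattern):
        self.pattern = list(pattern)

    def predict(self, X):
        reps = -(-len(X) // len(self.pattern))
        flags = (self.pattern * reps)[: len(X)]
        return np.array([POSITIVE_LABEL if f else NEGATIVE_LABEL for f in flags])


class TestStepAccuracy:
    def test_pooled_field_example(self):
        assert cs.step_accuracy(39 + 6 + 20, 45 + 6 + 24) == pytest.approx(86.67, abs=0.005)

    def test_exact_match_is_100(self):
        assert cs.step_accuracy(42, 42) == 100.0

    def test_overcount_formula(self):
        assert cs.step_accuracy(50, 40) == pytest.approx(75.0)

    def test_symmetric_in_error_sign(self):
        assert cs.step_accuracy(35, 40) == cs.step_accuracy(45, 40)

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError):
            cs.step_accuracy(5, 0)


class TestCohortReport:
    def test_field_trio_aggregations(self):
        results = [
            cs.StepCountResult("C8", 39, 45),
            cs.StepCountResult("C9", 6, 6),
            cs.StepCountResult("C10", 20, 24),
        ]
        rep = cs.cohort_step_report(results)
        assert rep.pooled_accuracy_pct == pytest.approx(86.67, abs=0.005)
        assert rep.mean_accuracy_pct == pytest.approx(90.0, abs=0.005)

    def test_all_perfect(self):
        rep = cs.cohort_step_report([cs.StepCountResult(f"C{i}", 10, 10) for i in range(3)])
        assert rep.pooled_accuracy_pct == rep.mean_accuracy_pct == 100.0

    def test_single_animal_pooled_equals_mean(self):
        rep = cs.cohort_step_report([cs.StepCountResult("C1", 18, 20)])
        assert rep.pooled_accuracy_pct == rep.mean_accuracy_pct

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.cohort_step_report([])


def rest_stream(duration=30.0, cfg=None, seed=0):
    cfg = cfg or cs.SimConfig()
    sch = cs.BehaviorSchedule(
        segments=[(0.0, duration, BehaviorLabel.STANDING_RESTING)],
        total_duration_s=duration,
    )
    stream, _ = cs.synthesize_imu(sch, cfg, seed=seed)
    return stream


class TestCountSteps:
    def test_always_negative_detector_counts_zero(self):
        events = cs.count_steps(StubDetector([False]), rest_stream())
        assert events.step_count == 0 and events.runs == []

    def test_isolated_positive_windows_per_window_rule(self):
        stream = rest_stream(12.0)
        spec = cs.StepWindowSpec(counting_rule="per_window")
        events = cs.count_steps(StubDetector([True, False]), stream, spec)
        assert events.step_count == 6
        assert len(events.runs) == 6
        assert all(e - s == pytest.approx(1.0) for s, e in events.runs)

    def test_per_run_rule_counts_runs(self):
        stream = rest_stream(12.0)
        spec = cs.StepWindowSpec(counting_rule="per_run")
        events = cs.count_steps(StubDetector([True, True, False]), stream, spec)
        assert events.step_count == 4

    def test_merge_gap_windows_joins_runs(self):
        stream = rest_stream(12.0)
        spec = cs.StepWindowSpec(counting_rule="per_run", merge_gap_windows=1)
        events = cs.count_steps(StubDetector([True, False]), stream, spec)
        assert events.step_count == 1
        assert len(events.runs) == 1

    def test_stream_shorter_than_window_warns(self):
        stream = rest_stream(30.0)
        with pytest.warns(UserWarning):
            events = cs.count_steps(
                StubDetector([True]), stream, cs.StepWindowSpec(length_s=60.0)
            )
        assert events.step_count == 0

    def test_recovers_twenty_steps_in_fifteen_minutes(self, step_detector):
        # walking bouts totalling 20 gait cycles inside a 15-min trace
        cfg = cs.SimConfig()
        sch = cs.BehaviorSchedule(
            segments=[
                (0.0, 200.0, BehaviorLabel.STANDING_RESTING),
                (200.0, 208.0, BehaviorLabel.WALKING),  # 12 steps
                (208.0, 600.0, BehaviorLabel.GRAZING),
                (600.0, 605.4, BehaviorLabel.WALKING),  # 8 steps
                (605.4, 900.0, BehaviorLabel.LYING_RESTING),
            ],
            total_duration_s=900.0,
        )
        stream, true_steps = cs.synthesize_imu(sch, cfg, seed=6)
        assert true_steps.size == 20
        events = cs.count_steps(step_detector, stream)
        assert abs(events.step_count - 20) <= 3

    def test_counts_invariant_to_prepended_rest(self, step_detector):
        cfg = cs.SimConfig(imu_noise_g=0.0, rest_noise_g=0.0,
                           gyro_noise_dps=0.0, mag_noise=0.0)
        walk = cs.BehaviorSchedule(
            segments=[(0.0, 20.0, BehaviorLabel.WALKING)], total_duration_s=20.0
        )
        padded = cs.BehaviorSchedule(
            segments=[
                (0.0, 10.0, BehaviorLabel.STANDING_RESTING),
                (10.0, 30.0, BehaviorLabel.WALKING),
            ],
            total_duration_s=30.0,
        )
        s1, _ = cs.synthesize_imu(walk, cfg, seed=0)
        s2, _ = cs.synthesize_imu(padded, cfg, seed=0)
        c1 = cs.count_steps(step_detector, s1).step_count
        c2 = cs.count_steps(step_detector, s2).step_count
        assert c1 == c2

    def test_featurization_identical_to_feature_extraction(self, step_detector):
        stream = rest_stream(10.0)
        spec = cs.WindowSpec(length_s=1.0)
        wins = cs.segment_windows(stream, [], spec)
        direct = cs.batch_features(np.stack([w.samples for w in wins]), 1.0 / 20.0)
        single = np.stack(
            [cs.extract_features(w, 1.0 / 20.0).values for w in wins]
        )
        np.testing.assert_array_equal(direct, single)


class TestDetectorTraining:
    def test_separable_training_fits_perfectly(self, default_config):
        train = cs.generate_cohort(1, default_config, 900.0, base_seed=300)
        m = cs.step_training_matrix(train)
        det = cs.train_step_detector(m, seed=0)
        rep = cs.evaluate(m.labels, det.predict(m.X))
        assert rep.sensitivity_pct[POSITIVE_LABEL] > 99.0

    def test_same_seed_identical_decisions(self, default_config):
        train = cs.generate_cohort(1, default_config, 900.0, base_seed=300)
        m = cs.step_training_matrix(train)
        d1 = cs.train_step_detector(m, seed=1)
        d2 = cs.train_step_detector(m, seed=1)
        assert list(d1.predict(m.X)) == list(d2.predict(m.X))

    def test_single_class_rejected(self, default_config):
        train = cs.generate_cohort(1, default_config, 900.0, base_seed=300)
        m = cs.step_training_matrix(train)
        m.labels = [NEGATIVE_LABEL] * len(m.labels)
        with pytest.raises(ValueError):
            cs.train_step_detector(m)

    def test_held_out_window_precision_and_sensitivity(self, step_detector, default_config):
        ds = cs.generate_dataset(default_config, 1800.0, seed=500, animal_id="C9")
        m = cs.step_training_matrix([ds])
        rep = cs.evaluate(m.labels, step_detector.predict(m.X))
        assert rep.sensitivity_pct[POSITIVE_LABEL] > 90.0
        assert rep.precision_pct[POSITIVE_LABEL] > 90.0
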