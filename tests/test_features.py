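"""Window segmentation and the seven per-channel features."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import collarsense as cs
from collarsense.features import CHANNELS
from collarsense.labels import BehaviorLabel
from tests.oracles import feature_oracle


def window_from_channel(x):
    """Replicate one channel across all 9 rows of a window."""
    return np.tile(np.asarray(x, float), (len(CHANNELS), 1))


class TestExtractFeatures:
    def test_constant_series(self):
        fv = cs.extract_features(window_from_channel([1.0, 1, 1, 1]), dt_s=1.0)
        np.testing.assert_allclose(fv.values[:7], [1, 0, 1, 0, 0, 4, 4], atol=1e-12)

    def test_alternating_series(self):
        fv = cs.extract_features(window_from_channel([1.0, -1, 1, -1]), dt_s=1.0)
        np.testing.assert_allclose(fv.values[:7], [0, 1, 1, 0, -2, 4, 4], atol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.integers(min_value=2, max_value=64),
            elements=st.floats(min_value=-10, max_value=10),
        ),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_matches_brute_force_oracle(self, x, dt):
        # numerically-constant windows exercise the degenerate rule instead
        # (tested explicitly above); here both moments must be well defined
        assume(np.var(x) > 1e-12 * (1.0 + np.max(np.abs(x)) ** 2))
        fv = cs.extract_features(window_from_channel(x), dt_s=dt)
        expected = feature_oracle(x, dt)
        for ch in range(len(CHANNELS)):
            np.testing.assert_allclose(
                fv.values[ch * 7 : (ch + 1) * 7], expected, atol=1e-9, rtol=1e-9
            )

    def test_rms_identity(self, rng):
        x = rng.normal(size=(9, 50))
        fv = cs.extract_features(x, dt_s=0.05).values.reshape(9, 7)
        # F3² = F1² + F2 and F6 = n·F3² under population conventions
        np.testing.assert_allclose(fv[:, 2] ** 2, fv[:, 0] ** 2 + fv[:, 1], atol=1e-9)
        np.testing.assert_allclose(fv[:, 5], 50 * fv[:, 2] ** 2, atol=1e-9)

    def test_translation_invariance_and_scaling(self, rng):
        x = rng.normal(size=40)
        early = cs.LabeledWindow(0.0, window_from_channel(x), None)
        late = cs.LabeledWindow(500.0, window_from_channel(x), None)
        a = cs.extract_features(early, dt_s=0.1).values
        b = cs.extract_features(late, dt_s=0.1).values
        np.testing.assert_array_equal(a, b)
        scaled = cs.extract_features(window_from_channel(3.0 * x), dt_s=0.1).values
        f = a.reshape(9, 7)
        g = scaled.reshape(9, 7)
        np.testing.assert_allclose(g[:, 0], 3.0 * f[:, 0], atol=1e-9)  # F1 linear
        np.testing.assert_allclose(g[:, 6], 3.0 * f[:, 6], atol=1e-9)  # F8 linear
        np.testing.assert_allclose(g[:, 1], 9.0 * f[:, 1], rtol=1e-9)  # F2 quadratic
        np.testing.assert_allclose(g[:, 5], 9.0 * f[:, 5], rtol=1e-9)  # F6 quadratic

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            cs.extract_features(window_from_channel([1.0]), dt_s=1.0)


def make_stream(duration=60.0, rate=20.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    return cs.SensorStream(
        t_s=np.arange(n) / rate,
        data=rng.normal(size=(9, n)),
        sample_rate_hz=rate,
        animal_id="C1",
    )


class TestSegmentWindows:
    def test_window_count(self):
        stream = make_stream(60.0)
        wins = cs.segment_windows(
            stream, [(0.0, 60.0, BehaviorLabel.GRAZING)], cs.WindowSpec()
        )
        assert len(wins) == 6
        assert all(w.label is BehaviorLabel.GRAZING for w in wins)

    def test_strict_majority_label(self):
        stream = make_stream(10.0)
        wins = cs.segment_windows(
            stream,
            [(0.0, 7.0, BehaviorLabel.WALKING), (7.0, 10.0, BehaviorLabel.FEEDING)],
            cs.WindowSpec(),
        )
        assert wins[0].label is BehaviorLabel.WALKING

    def test_even_split_is_unlabeled(self):
        stream = make_stream(10.0)
        wins = cs.segment_windows(
            stream,
            [(0.0, 5.0, BehaviorLabel.WALKING), (5.0, 10.0, BehaviorLabel.FEEDING)],
            cs.WindowSpec(),
        )
        assert wins[0].label is None

    def test_overlapping_intervals_rejected(self):
        stream = make_stream(10.0)
        with pytest.raises(ValueError):
            cs.segment_windows(
                stream,
                [(0.0, 6.0, BehaviorLabel.WALKING), (5.0, 10.0, BehaviorLabel.FEEDING)],
                cs.WindowSpec(),
            )

    def test_window_longer_than_stream_warns_and_returns_empty(self):
        stream = make_stream(5.0)
        with pytest.warns(UserWarning):
            wins = cs.segment_windows(stream, [], cs.WindowSpec(length_s=10.0))
        assert wins == []

    def test_overlap_fraction_shrinks_the_stride(self):
        stream = make_stream(60.0)
        wins = cs.segment_windows(
            stream,
            [(0.0, 60.0, BehaviorLabel.GRAZING)],
            cs.WindowSpec(overlap_fraction=0.5),
        )
        assert len(wins) == 11
        assert wins[1].start_s == pytest.approx(5.0)


class TestBuildFeatureMatrix:
    def test_shape_and_order(self):
        stream = make_stream(60.0)
        wins = cs.segment_windows(
            stream, [(0.0, 60.0, BehaviorLabel.GRAZING)], cs.WindowSpec()
        )
        m = cs.build_feature_matrix(wins, dt_s=0.05)
        assert m.X.shape == (6, 63)
        assert m.feature_names[0] == "ax_F1" and m.feature_names[-1] == "mz_F8"

    def test_permutation_invariant(self, rng):
        stream = make_stream(60.0)
        wins = cs.segment_windows(
            stream, [(0.0, 60.0, BehaviorLabel.GRAZING)], cs.WindowSpec()
        )
        shuffled = list(wins)
        rng.shuffle(shuffled)
        a = cs.build_feature_matrix(wins, 0.05)
        b = cs.build_feature_matrix(shuffled, 0.05)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.start_s, b.start_s)

    def test_animal_ids_preserved(self):
        s1, s2 = make_stream(30.0, seed=1), make_stream(30.0, seed=2)
        s2.animal_id = "C2"
        wins = []
        for s in (s1, s2):
            wins += cs.segment_windows(
                s, [(0.0, 30.0, BehaviorLabel.FEEDING)], cs.WindowSpec()
            )
        m = cs.build_feature_matrix(wins, 0.05)
        assert m.animal_ids == ["C1"] * 3 + ["C2"] * 3

    def test_all_unlabeled_rejected(self):
        stream = make_stream(20.0)
        wins = cs.segment_windows(stream, [], cs.WindowSpec())
        with pytest.raises(ValueError):
            cs.build_feature_matrix(wins, 0.05)
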