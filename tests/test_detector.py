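import numpy as np
import pytest

from classtalk.detector import (
    DetectorSpec,
    build_detector,
    loso_run,
    predict_track,
    save_detector,
    load_detector,
    smooth_track,
    train_detector,
)
from classtalk.features import CHANNELS, FeatureSeries, apply_normalize, fit_normalize
from classtalk.intervals import IntervalTrack, intervals_from_mask, rasterize_intervals
from tests.conftest import random_track

FAST = dict(hidden_units=8, epochs=6, learning_rate=0.05, window_bins=100, batch_size=8)


def _toy_series(rng, labels, child="c"):
    """A 15-channel series where adult area + speech track the labels."""
    T = len(labels)
    X = rng.normal(0, 0.05, size=(T, len(CHANNELS)))
    X[:, CHANNELS.index("adult_area")] = labels * 0.08 + rng.normal(0, 0.002, T)
    X[:, CHANNELS.index("speech_active")] = labels
    return FeatureSeries(child, T * 250, X,
                         {"adult": np.zeros(T, bool), "peer": np.zeros(T, bool)})


def _toy_cohort(rng, n_children=4, T=600):
    cohort = []
    for i in range(n_children):
        y = (np.convolve(rng.random(T) < 0.1, np.ones(16), "same") > 0).astype(float)
        series = _toy_series(rng, y, child=f"c{i}")
        track = intervals_from_mask(y, partner_class="adult")
        cohort.append((f"c{i}", series, track))
    return cohort


class TestSpecAndBuild:
    def test_full_and_reduced_input_widths(self):
        assert build_detector(DetectorSpec("adult", "full")).net.n_features == 15
        assert build_detector(DetectorSpec("peer", "reduced")).net.n_features == 2

    def test_reduced_set_only_sees_partner_area_and_speech(self):
        idx = DetectorSpec("peer", "reduced").feature_indices()
        assert [CHANNELS[i] for i in idx] == ["peer_area", "speech_active"]
        idx = DetectorSpec("adult", "reduced").feature_indices()
        assert [CHANNELS[i] for i in idx] == ["adult_area", "speech_active"]

    def test_same_seed_gives_identical_initial_parameters(self):
        a = build_detector(DetectorSpec("adult", seed=5))
        b = build_detector(DetectorSpec("adult", seed=5))
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError):
            DetectorSpec("adult", "medium")

    def test_forward_on_zero_input_is_valid_simplex(self):
        model = build_detector(DetectorSpec("adult", "full", hidden_units=6))
        probs = model.net.predict_proba(np.zeros((20, 15)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()


class TestTraining:
    def test_one_epoch_changes_parameters(self, rng):
        model = build_detector(DetectorSpec("adult", "full", hidden_units=6, epochs=1,
                                            window_bins=50, batch_size=4))
        before = {k: v.copy() for k, v in model.net.params.items()}
        y = rng.integers(0, 2, 200).astype(float)
        train_detector(model, [(_toy_series(rng, y), y)])
        assert any(not np.array_equal(before[k], model.net.params[k]) for k in before)

    def test_loss_decreases_on_separable_data(self, rng):
        cohort = _toy_cohort(rng, 3)
        model = build_detector(DetectorSpec("adult", "full", **FAST))
        sessions = [(s, rasterize_intervals(t, s.session_ms).astype(float))
                    for _, s, t in cohort]
        train_detector(model, sessions)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_label_length_mismatch_rejected(self, rng):
        model = build_detector(DetectorSpec("adult", "full", hidden_units=4))
        with pytest.raises(ValueError, match="length"):
            train_detector(model, [(_toy_series(rng, np.zeros(50)), np.zeros(49))])

    def test_all_zero_labels_collapse_to_empty_track(self, rng):
        model = build_detector(DetectorSpec("adult", "full", **FAST))
        series = _toy_series(rng, np.zeros(400))
        train_detector(model, [(series, np.zeros(400))])
        track = smooth_track(predict_track(model, series))
        assert len(track) == 0

    def test_channel_count_mismatch_at_predict_rejected(self, rng):
        model = build_detector(DetectorSpec("adult", "full", hidden_units=4))
        bad = FeatureSeries("c", 1000, np.zeros((4, 7)),
                            {"adult": np.zeros(4, bool), "peer": np.zeros(4, bool)})
        with pytest.raises(ValueError, match="channels"):
            predict_track(model, bad)


class TestSmoothing:
    def test_short_lone_interval_deleted(self):
        track = IntervalTrack("adult", ((0, 500),), "predicted")
        assert smooth_track(track).intervals == ()

    def test_short_gap_merged_before_deletion(self):
        track = IntervalTrack("adult", ((0, 2000), (2400, 4000)), "predicted")
        assert smooth_track(track).intervals == ((0, 4000),)

    def test_negative_min_duration_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(IntervalTrack("adult"), -1)

    def test_idempotent_with_no_short_interval_or_gap(self, rng):
        for _ in range(1000):
            track = random_track(rng, n_max=15, horizon_ms=60_000)
            out = smooth_track(track)
            assert smooth_track(out) == out
            for a, b in out.intervals:
                assert b - a >= 1000
            for (_, b1), (a2, _) in zip(out.intervals, out.intervals[1:]):
                assert a2 - b1 >= 1000


class TestRoundTrip:
    def test_trajectory_encoding_examples(self):
        track = intervals_from_mask(np.array([0, 1, 1, 0]), partner_class="adult")
        assert track.intervals == ((250, 750),)
        assert intervals_from_mask(np.zeros(10)).intervals == ()

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = build_detector(DetectorSpec("peer", "reduced", hidden_units=5, epochs=2,
                                            window_bins=50, batch_size=4))
        y = (rng.random(150) < 0.3).astype(float)
        series = _toy_series(rng, y)
        stats = fit_normalize([series])
        train_detector(model, [(apply_normalize(series, stats), y)], norm_stats=stats)
        path = tmp_path / "model.npz"
        save_detector(path, model)
        loaded = load_detector(path)
        assert loaded.spec == model.spec
        for k in model.net.params:
            np.testing.assert_array_equal(loaded.net.params[k], model.net.params[k])
        np.testing.assert_array_equal(loaded.norm_stats.center, stats.center)


class TestLoso:
    def test_two_child_cohort_trains_on_the_other_child(self, rng):
        cohort = _toy_cohort(rng, 2, T=300)
        res = loso_run(cohort, DetectorSpec("adult", "full", **FAST))
        assert set(res) == {"c0", "c1"}
        # each fold's norm stats come from exactly the other child's series
        stats0 = res["c0"]["model"].norm_stats
        expected = fit_normalize([cohort[1][1]])
        np.testing.assert_allclose(stats0.center, expected.center)

    def test_single_child_rejected(self, rng):
        with pytest.raises(ValueError):
            loso_run(_toy_cohort(rng, 1, T=100), DetectorSpec("adult", "full", **FAST))

    def test_heldout_perturbation_never_changes_fold_training_stats(self, rng):
        """Leakage probe: corrupting the held-out child's features leaves its
        fold's normalization statistics untouched."""
        cohort = _toy_cohort(rng, 3, T=200)
        res = loso_run(cohort, DetectorSpec("adult", "full", hidden_units=4, epochs=1,
                                            window_bins=100, batch_size=4))
        cid, series, track = cohort[0]
        perturbed = series.with_channels(series.channels + 1000.0)
        cohort2 = [(cid, perturbed, track)] + cohort[1:]
        res2 = loso_run(cohort2, DetectorSpec("adult", "full", hidden_units=4, epochs=1,
                                              window_bins=100, batch_size=4))
        np.testing.assert_array_equal(
            res["c0"]["model"].norm_stats.center, res2["c0"]["model"].norm_stats.center
        )
        np.testing.assert_array_equal(
            res["c0"]["model"].norm_stats.scale, res2["c0"]["model"].norm_stats.scale
        )
        for k in res["c0"]["model"].net.params:
            np.testing.assert_array_equal(
                res["c0"]["model"].net.params[k], res2["c0"]["model"].net.params[k]
            )
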