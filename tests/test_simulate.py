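import dataclasses
import math

import numpy as np
import pytest

from classtalk.measures import cds_measures, interaction_measures, tokenize_utterance
from classtalk.simulate import (
    RefUtterance,
    SimConfig,
    build_vocabulary,
    corrupt_transcript,
    generate_cohort,
    generate_session,
)


class TestConfigValidation:
    def test_defaults_are_valid_and_peer_shorter_than_adult(self):
        cfg = SimConfig()
        cfg.validate()
        assert math.exp(cfg.peer_dur_logmean) < math.exp(cfg.adult_dur_logmean)

    @pytest.mark.parametrize(
        "field, value",
        [
            ("session_minutes", 0.0),
            ("adult_rate", -1.0),
            ("occlusion_prob", 1.5),
            ("wer_del", -0.1),
            ("adult_rate", 3000.0),  # > 1 onset per 250 ms bin
            ("vocab_size", 3),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(SimConfig(), **{field: value}).validate()

    def test_wer_probabilities_must_sum_below_one(self):
        with pytest.raises(ValueError):
            SimConfig(wer_del=0.7, wer_sub=0.5).validate()


class TestGenerateSession:
    def test_zero_rates_give_empty_world(self):
        cfg = SimConfig(session_minutes=5, adult_rate=0, peer_rate=0,
                        background_speech_rate=0, false_face_rate=0,
                        staff_face_rate=0, seed=1)
        s = generate_session(cfg)
        assert len(s.truth_adult) == 0 and len(s.truth_peer) == 0
        assert s.reference_utterances == [] and s.asr_segments == []
        assert s.bookkeeping["cds"]["adult"].tnu == 0
        assert s.bookkeeping["cds"]["peer"].tnw == 0

    def test_same_seed_gives_identical_sessions(self):
        cfg = SimConfig(session_minutes=6, seed=9)
        a, b = generate_session(cfg, "x"), generate_session(cfg, "x")
        assert a.reference_utterances == b.reference_utterances
        assert a.face_detections == b.face_detections
        assert a.face_matches == b.face_matches
        assert a.asr_segments == b.asr_segments
        assert a.truth_adult == b.truth_adult and a.truth_peer == b.truth_peer

    def test_interaction_counts_follow_the_point_process_rate(self):
        """Mean realized count over replicates sits within 3 SE of the Poisson
        expectation (durations kept short so same-class merging is negligible)."""
        n_rep, rate, minutes = 200, 2.0, 40.0
        counts = [
            len(generate_session(SimConfig(
                session_minutes=minutes, adult_rate=rate,
                adult_dur_logmean=math.log(4.0), adult_dur_logsd=0.3,
                seed=1000 + i)).truth_adult)
            for i in range(n_rep)
        ]
        expected = rate * minutes / 10
        se = math.sqrt(expected / n_rep)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_realized_counts_pass_poisson_goodness_of_fit(self):
        """Chi-square GOF of replicate counts against Poisson(rate*T) at alpha=0.01."""
        from scipy import stats as sps

        lam = 3.0 * 20.0 / 10  # rate 3/10min over 20 min
        counts = np.array([
            len(generate_session(SimConfig(
                session_minutes=20.0, peer_rate=0, adult_rate=3.0,
                adult_dur_logmean=math.log(3.0), adult_dur_logsd=0.3,
                seed=5000 + i)).truth_adult)
            for i in range(200)
        ])
        edges = [-0.5, 2.5, 4.5, 6.5, 8.5, np.inf]
        obs = np.histogram(counts, bins=edges)[0]
        cdf = sps.poisson(lam).cdf
        probs = np.diff([0] + [cdf(e) for e in edges[1:-1]] + [1])
        chi2 = ((obs - 200 * probs) ** 2 / (200 * probs)).sum()
        assert sps.chi2(len(obs) - 1).sf(chi2) > 0.01

    def test_peer_interactions_are_shorter_than_adult_ones(self):
        durs = {"adult": [], "peer": []}
        for i in range(30):
            s = generate_session(SimConfig(session_minutes=40, seed=200 + i))
            durs["adult"] += list(s.truth_adult.durations_ms())
            durs["peer"] += list(s.truth_peer.durations_ms())
        assert np.median(durs["peer"]) < np.median(durs["adult"])

    def test_cds_utterances_lie_inside_matching_truth_intervals(self, small_session):
        s = small_session
        for u in s.reference_utterances:
            if u.cds_label == "adult_cds":
                assert s.truth_adult.intersects(u.start, u.end)
            elif u.cds_label == "peer_cds":
                assert s.truth_peer.intersects(u.start, u.end)
            else:
                assert not s.truth_adult.intersects(u.start, u.end)
                assert not s.truth_peer.intersects(u.start, u.end)

    def test_true_partner_faces_are_larger_than_background_faces(self, small_session):
        s = small_session
        in_truth, outside = [], []
        for d in s.face_detections:
            inside = s.truth_adult.intersects(d.t, d.t + 1) or s.truth_peer.intersects(
                d.t, d.t + 1
            )
            (in_truth if inside else outside).append(d.area)
        if in_truth and outside:
            assert np.median(in_truth) > np.median(outside)

    def test_bookkeeping_roundtrips_through_the_measures_module(self):
        """Recomputing the measures from the reference transcript reproduces
        the generator's bookkeeping exactly, across random configs."""
        rng = np.random.default_rng(77)
        for i in range(50):
            cfg = SimConfig(
                session_minutes=float(rng.uniform(3, 8)),
                adult_rate=float(rng.uniform(0, 4)),
                peer_rate=float(rng.uniform(0, 5)),
                wer_del=float(rng.uniform(0, 0.5)),
                occlusion_prob=float(rng.uniform(0, 0.5)),
                seed=int(rng.integers(0, 2**31)),
            )
            s = generate_session(cfg)
            groups = {
                "adult": [u for u in s.reference_utterances
                          if u.speaker_class != "focal" and u.cds_label == "adult_cds"],
                "peer": [u for u in s.reference_utterances
                         if u.speaker_class != "focal" and u.cds_label == "peer_cds"],
                "focal": [u for u in s.reference_utterances
                          if u.speaker_class == "focal" and u.cds_label != "non_cds"],
            }
            for cls, utts in groups.items():
                recomputed = cds_measures(
                    [tokenize_utterance(" ".join(u.words)) for u in utts],
                    cfg.session_minutes,
                )
                assert recomputed == s.bookkeeping["cds"][cls]
            for cls, track in (("adult", s.truth_adult), ("peer", s.truth_peer)):
                assert interaction_measures(track, cfg.session_minutes) == \
                    s.bookkeeping["interaction"][cls]


class TestGenerateCohort:
    def test_cohort_of_thirteen_children_with_distinct_ids(self):
        sessions = generate_cohort(SimConfig(session_minutes=2, seed=3), 13)
        assert len(sessions) == 13
        assert len({s.child_id for s in sessions}) == 13

    def test_single_child_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimConfig(), 1)

    def test_same_master_seed_gives_identical_cohorts(self):
        a = generate_cohort(SimConfig(session_minutes=2, seed=8), 3)
        b = generate_cohort(SimConfig(session_minutes=2, seed=8), 3)
        for sa, sb in zip(a, b):
            assert sa.reference_utterances == sb.reference_utterances
            assert sa.face_detections == sb.face_detections


def _ref_utts(words_per_utt, n_utts, dur_ms=2000):
    vocab = build_vocabulary(50)
    rng = np.random.default_rng(0)
    out = []
    for i in range(n_utts):
        words = tuple(rng.choice(vocab, size=words_per_utt))
        out.append(RefUtterance("adult", i * 3000, i * 3000 + dur_ms, words, "adult_cds"))
    return out


class TestCorruptTranscript:
    def test_zero_corruption_is_token_identical(self):
        ref = _ref_utts(4, 10)
        segs = corrupt_transcript(ref, 0.0, 0.0, seed=1)
        out_tokens = [w.token for s in segs for w in s.words]
        assert out_tokens == [w for u in ref for w in u.words]

    def test_full_deletion_emits_nothing(self):
        assert corrupt_transcript(_ref_utts(3, 5), 1.0, 0.0, seed=1) == []

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            corrupt_transcript([], 0.6, 0.6, seed=1)

    def test_substituted_words_have_lower_confidence(self):
        ref = _ref_utts(6, 30)
        segs = corrupt_transcript(ref, 0.0, 0.5, seed=2)
        original = {w for u in ref for w in u.words}
        confs = {"kept": [], "sub": []}
        for s in segs:
            for i, w in enumerate(s.words):
                confs["sub" if w.conf < 0.7 else "kept"].append(w.conf)
        assert confs["sub"] and max(confs["sub"]) < min(confs["kept"])

    def test_word_survival_matches_binomial_expectation(self):
        """With deletion probability 0.3 the surviving word count averages 0.7
        of the reference, within 3 SE over 50 seeds."""
        ref = _ref_utts(10, 200)  # 2000 reference words per replicate
        n_ref = sum(len(u.words) for u in ref)
        ratios = []
        for seed in range(50):
            segs = corrupt_transcript(ref, 0.3, 0.0, seed=seed)
            ratios.append(sum(len(s.words) for s in segs) / n_ref)
        se = math.sqrt(0.3 * 0.7 / n_ref / 50)
        assert abs(np.mean(ratios) - 0.7) < 3 * se

    def test_punctuation_boundaries_preserved(self):
        ref = _ref_utts(4, 6)
        segs = corrupt_transcript(ref, 0.0, 0.0, seed=3)
        n_sentences = sum(s.punctuated_text.count(".") for s in segs)
        assert n_sentences == len(ref)
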