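"""Synthetic classroom sessions for training, calibration and testing.

Real first-person classroom recordings are private and their featurization
ran through paid cloud services, so this module generates complete sessions
with the same statistical structure: ground-truth interaction tracks, a
face-detection/recognition stream at the 500 ms native rate, diarized ASR
segments with word timings and confidences, and an uncorrupted reference
transcript with exact bookkeeping measures.

The generative model, per partner class:

* interaction onsets follow a homogeneous Poisson process (a configured
  rate per 10 minutes) with log-normal durations; overlapping same-class
  intervals are merged.  Defaults encode the observed contrast — adult
  interactions long and infrequent, peer interactions sparse and *short*.
* during a true interaction the partner's face is emitted on the 500 ms
  grid with probability 1 - occlusion_prob, with a large (near) bounding
  box; background false faces appear outside interactions at a configured
  rate with small (far) boxes.  Adult partners carry a high-similarity
  recognition match to the enrolled teacher; unenrolled faces resolve to
  the peer class downstream.  Research-staff faces (matched, class
  other_adult) are injected so the ingest removal path is exercised.
* partner speech fills interactions (this is the child-directed speech),
  the focal child replies inside interactions with a configured
  probability, and background speech occurs outside interactions so the
  diarization stage sees true negatives.
* the ASR output underestimates the transcript: each word is independently
  deleted with probability wer_del or replaced by a random vocabulary word
  with probability wer_sub (with depressed confidence); utterances losing
  all words disappear.

All randomness derives from one master seed through named spawned streams,
so identical configs give byte-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ingest import AsrSegment, FaceDetection, FaceMatch, Word
from .intervals import IntervalTrack, intersection_ms
from .measures import (
    InteractionMeasures,
    MeasureSet,
    cds_measures,
    interaction_measures,
    tokenize_utterance,
)

__all__ = [
    "SimConfig",
    "RefUtterance",
    "SyntheticSession",
    "build_vocabulary",
    "generate_session",
    "generate_cohort",
    "corrupt_transcript",
]

# ------------------------------------------------------------------ vocabulary

_BASE_WORDS = (
    "the a and you i it is to we go look at this that here no yes what do "
    "play with me my your can want see come sit down up on in out one two "
    "three big little red blue green block truck doll book ball water snack "
    "time friend teacher please thank good okay now more all done put give "
    "take turn share nice help let us make build draw color cut paper glue "
    "outside inside table chair clean hands wash story song day"
).split() + ["you're", "don't", "it's", "let's", "that's", "i'm", "we're", "can't"]

_CONSONANTS = "bdfgklmnprst"
_VOWELS = "aeiou"


def build_vocabulary(vocab_size: int) -> list[str]:
    """A fixed vocabulary: common classroom words, padded with CVCV pseudo-words."""
    if vocab_size < 10:
        raise ValueError("vocab_size must be at least 10")
    vocab = list(dict.fromkeys(_BASE_WORDS))
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    seen = set(vocab)
    for a in syllables:
        for b in syllables:
            if len(vocab) >= vocab_size:
                break
            word = a + b
            if word not in seen:
                seen.add(word)
                vocab.append(word)
        if len(vocab) >= vocab_size:
            break
    if len(vocab) < vocab_size:
        raise ValueError(f"vocab_size {vocab_size} exceeds constructible vocabulary")
    return vocab[:vocab_size]


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / (np.arange(1, n + 1) + 2.7)
    return w / w.sum()


# ---------------------------------------------------------------------- config


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic session.

    Rates are per 10 minutes (interactions) or per minute (faces, background
    speech); durations are parameterized on the log scale in seconds.  The
    defaults encode ~40-minute morning sessions in which adult interactions
    are long and infrequent (median 90 s) while peer interactions are sparse
    and short (median 20 s).
    """

    session_minutes: float = 40.0
    adult_rate: float = 1.2  # interactions / 10 min
    adult_dur_logmean: float = math.log(90.0)  # log seconds
    adult_dur_logsd: float = 0.6
    peer_rate: float = 2.0
    peer_dur_logmean: float = math.log(20.0)
    peer_dur_logsd: float = 0.6
    occlusion_prob: float = 0.2
    false_face_rate: float = 4.0  # background faces / min
    staff_face_rate: float = 0.5  # research-staff faces / min
    word_rate: float = 2.5  # words / s of speech
    wer_del: float = 0.3
    wer_sub: float = 0.1
    vocab_size: int = 200
    background_speech_rate: float = 2.0  # utterances / min outside interactions
    focal_speech_prob: float = 0.7  # P(focal child speaks during an interaction)
    seed: int = 0

    def validate(self) -> None:
        if not self.session_minutes > 0:
            raise ValueError("session_minutes must be positive")
        for name in ("adult_rate", "peer_rate", "false_face_rate", "staff_face_rate",
                     "word_rate", "background_speech_rate"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative")
        for name in ("occlusion_prob", "wer_del", "wer_sub", "focal_speech_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.wer_del + self.wer_sub > 1.0:
            raise ValueError("wer_del + wer_sub must not exceed 1")
        # one onset per 250 ms bin is the densest supported regime
        for name in ("adult_rate", "peer_rate"):
            if getattr(self, name) > 2400.0:
                raise ValueError(f"{name} implies > 1 onset per 250 ms bin; unsupported")
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be at least 10")


# ------------------------------------------------------------------- utterance


@dataclass(frozen=True)
class RefUtterance:
    """Uncorrupted reference utterance with its generative CDS assignment."""

    speaker_class: str  # adult | peer | focal
    start: int  # ms
    end: int  # ms
    words: tuple[str, ...]
    cds_label: str  # adult_cds | peer_cds | non_cds


@dataclass(frozen=True)
class SyntheticSession:
    child_id: str
    session_ms: int
    truth_adult: IntervalTrack
    truth_peer: IntervalTrack
    face_detections: list[FaceDetection]
    face_matches: list[FaceMatch]
    identity_map: dict[str, str]  # face_id -> participant class
    asr_segments: list[AsrSegment]
    reference_utterances: list[RefUtterance]
    bookkeeping: dict
    config: SimConfig


# ------------------------------------------------------------------ generation


def _draw_intervals(rng, rate_per_10min, logmean, logsd, session_ms, partner):
    n = rng.poisson(rate_per_10min * (session_ms / 600_000.0))
    onsets = np.sort(rng.uniform(0, session_ms, size=n))
    ivs = []
    for on in onsets:
        dur_ms = rng.lognormal(logmean, logsd) * 1000.0
        off = min(session_ms, int(round(on + dur_ms)))
        on = int(round(on))
        if off > on:
            ivs.append((on, off))
    return IntervalTrack.from_intervals(partner, ivs, source="reference")


def _speech_in_interval(rng, on, off, speaker, word_rate, vocab, probs,
                        gap_mean_ms, words_mean):
    """Alternating gap/utterance process inside [on, off)."""
    utts = []
    t = on + rng.exponential(gap_mean_ms)
    while True:
        n_words = 1 + rng.poisson(words_mean)
        dur = n_words / word_rate * 1000.0
        if t + dur > off:
            break
        words = tuple(rng.choice(vocab, size=n_words, p=probs))
        utts.append((speaker, int(round(t)), int(round(t + dur)), words))
        t = t + dur + rng.exponential(gap_mean_ms)
        if t >= off:
            break
    return utts


def _cds_label(start, end, truth_adult, truth_peer):
    if truth_adult.intersects(start, end):
        return "adult_cds"
    if truth_peer.intersects(start, end):
        return "peer_cds"
    return "non_cds"


def _random_bbox(rng, w_lo, w_hi):
    w = rng.uniform(w_lo, w_hi)
    h = min(w * rng.uniform(1.0, 1.4), 0.95)
    x = rng.uniform(0, 1 - w)
    y = rng.uniform(0, 1 - h)
    return (float(x), float(y), float(w), float(h))


def generate_session(config: SimConfig, child_id: str = "c00") -> SyntheticSession:
    """One complete synthetic session; deterministic given config.seed."""
    config.validate()
    session_ms = int(round(config.session_minutes * 60_000))
    ss = np.random.SeedSequence(config.seed)
    rng_int, rng_speech, rng_face, rng_corrupt = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    vocab = build_vocabulary(config.vocab_size)
    probs = _zipf_probs(len(vocab))

    truth_adult = _draw_intervals(
        rng_int, config.adult_rate, config.adult_dur_logmean, config.adult_dur_logsd,
        session_ms, "adult",
    )
    truth_peer = _draw_intervals(
        rng_int, config.peer_rate, config.peer_dur_logmean, config.peer_dur_logsd,
        session_ms, "peer",
    )

    # ---- speech: partner CDS inside intervals, focal replies, background talk
    raw_utts: list[tuple[str, int, int, tuple[str, ...]]] = []
    for track, speaker in ((truth_adult, "adult"), (truth_peer, "peer")):
        for on, off in track.intervals:
            raw_utts += _speech_in_interval(
                rng_speech, on, off, speaker, config.word_rate, vocab, probs,
                gap_mean_ms=1200.0, words_mean=2.2,
            )
            if rng_speech.random() < config.focal_speech_prob:
                raw_utts += _speech_in_interval(
                    rng_speech, on, off, "focal", config.word_rate, vocab, probs,
                    gap_mean_ms=2500.0, words_mean=1.5,
                )
    n_bg = rng_speech.poisson(config.background_speech_rate * config.session_minutes)
    for _ in range(n_bg):
        start = rng_speech.uniform(0, session_ms)
        n_words = 1 + rng_speech.poisson(2.2)
        end = start + n_words / config.word_rate * 1000.0
        start, end = int(round(start)), min(session_ms, int(round(end)))
        if end <= start:
            continue
        if (intersection_ms(truth_adult.intervals, start, end) > 0
                or intersection_ms(truth_peer.intervals, start, end) > 0):
            continue  # background talk is non-CDS by construction
        words = tuple(rng_speech.choice(vocab, size=n_words, p=probs))
        speaker = "adult" if rng_speech.random() < 0.5 else "peer"
        raw_utts.append((speaker, start, end, words))

    raw_utts.sort(key=lambda u: (u[1], u[2]))
    reference = [
        RefUtterance(speaker, start, end, words,
                     _cds_label(start, end, truth_adult, truth_peer))
        for speaker, start, end, words in raw_utts
    ]

    # ---- faces at the 500 ms native grid
    detections: list[FaceDetection] = []
    matches: list[FaceMatch] = []
    identity_map = {"teacher_1": "adult", "staff_1": "other_adult"}
    speech_spans = {
        "adult": [(u.start, u.end) for u in reference if u.speaker_class == "adult"],
        "peer": [(u.start, u.end) for u in reference if u.speaker_class == "peer"],
    }

    def partner_speaking(cls, t):
        return any(a <= t < b for a, b in speech_spans[cls])

    grid = range(0, session_ms, 500)
    for track, cls in ((truth_adult, "adult"), (truth_peer, "peer")):
        for on, off in track.intervals:
            for t in grid:
                if not on <= t < off:
                    continue
                if rng_face.random() < config.occlusion_prob:
                    continue
                bbox = _random_bbox(rng_face, 0.16, 0.30)
                mouth = (rng_face.uniform(55, 100) if partner_speaking(cls, t)
                         else rng_face.uniform(0, 45))
                detections.append(FaceDetection(
                    t=t, bbox=bbox,
                    yaw=rng_face.normal(0, 15), roll=rng_face.normal(0, 10),
                    pitch=rng_face.normal(0, 12),
                    mouth_open_conf=float(mouth),
                    eyes_open_conf=rng_face.uniform(70, 100),
                ))
                if cls == "adult":
                    matches.append(FaceMatch(
                        t=t, face_id="teacher_1",
                        similarity=rng_face.uniform(93, 100), bbox=bbox,
                    ))
    n_grid = len(grid)
    for rate, w_lo, w_hi, face_id in (
        (config.false_face_rate, 0.04, 0.12, None),
        (config.staff_face_rate, 0.08, 0.20, "staff_1"),
    ):
        n = rng_face.poisson(rate * config.session_minutes)
        for t in rng_face.choice(n_grid, size=n) * 500:
            t = int(t)
            bbox = _random_bbox(rng_face, w_lo, w_hi)
            detections.append(FaceDetection(
                t=t, bbox=bbox,
                yaw=rng_face.normal(0, 25), roll=rng_face.normal(0, 15),
                pitch=rng_face.normal(0, 15),
                mouth_open_conf=rng_face.uniform(0, 60),
                eyes_open_conf=rng_face.uniform(50, 100),
            ))
            if face_id is not None:
                matches.append(FaceMatch(
                    t=t, face_id=face_id,
                    similarity=rng_face.uniform(93, 100), bbox=bbox,
                ))
    detections.sort(key=lambda d: d.t)
    matches.sort(key=lambda m: m.t)

    # ---- ASR output: corrupted version of the reference transcript
    asr_segments = corrupt_transcript(
        reference, config.wer_del, config.wer_sub, rng=rng_corrupt, vocab=vocab
    )

    # ---- exact bookkeeping measures from the uncorrupted reference
    minutes = config.session_minutes
    by_class = {
        "adult": [u for u in reference
                  if u.speaker_class != "focal" and u.cds_label == "adult_cds"],
        "peer": [u for u in reference
                 if u.speaker_class != "focal" and u.cds_label == "peer_cds"],
        "focal": [u for u in reference
                  if u.speaker_class == "focal" and u.cds_label != "non_cds"],
    }
    bookkeeping = {
        "cds": {
            cls: cds_measures(
                [tokenize_utterance(" ".join(u.words)) for u in utts], minutes
            )
            for cls, utts in by_class.items()
        },
        "interaction": {
            "adult": interaction_measures(truth_adult, minutes),
            "peer": interaction_measures(truth_peer, minutes),
        },
        "n_reference_utterances": len(reference),
    }

    return SyntheticSession(
        child_id=child_id,
        session_ms=session_ms,
        truth_adult=truth_adult,
        truth_peer=truth_peer,
        face_detections=detections,
        face_matches=matches,
        identity_map=identity_map,
        asr_segments=asr_segments,
        reference_utterances=reference,
        bookkeeping=bookkeeping,
        config=config,
    )


def generate_cohort(config: SimConfig, n_children: int) -> list[SyntheticSession]:
    """Independent sessions for n_children, seeded from the master seed."""
    if n_children < 2:
        raise ValueError("a cohort needs at least 2 children (cross-validation)")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_children) % (2**31)
    return [
        generate_session(replace(config, seed=int(s)), child_id=f"c{i + 1:02d}")
        for i, s in enumerate(child_seeds)
    ]


# ------------------------------------------------------------------ corruption


def corrupt_transcript(
    reference: list[RefUtterance],
    wer_del: float,
    wer_sub: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    vocab: list[str] | None = None,
    vocab_size: int = 200,
) -> list[AsrSegment]:
    """Turn reference utterances into imperfect ASR segments.

    Each word is independently deleted with probability ``wer_del`` or
    replaced by a random vocabulary word with probability ``wer_sub``
    (substituted words get depressed confidence); utterances stripped of all
    words are dropped.  Surviving utterances keep their sentence-final
    punctuation and are grouped into segments: consecutive utterances by the
    same speaker separated by less than one second share a segment.
    """
    if not (0 <= wer_del <= 1 and 0 <= wer_sub <= 1 and wer_del + wer_sub <= 1):
        raise ValueError("wer_del and wer_sub must be probabilities with sum <= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if vocab is None:
        vocab = build_vocabulary(vocab_size)

    surviving: list[tuple[RefUtterance, list[Word]]] = []
    for u in reference:
        kept: list[tuple[str, float]] = []
        for w in u.words:
            r = rng.random()
            if r < wer_del:
                continue
            if r < wer_del + wer_sub:
                kept.append((str(rng.choice(vocab)), rng.uniform(0.35, 0.60)))
            else:
                kept.append((w, rng.uniform(0.75, 0.98)))
        if not kept:
            continue
        dur = u.end - u.start
        n = len(kept)
        words = [
            Word(
                token=tok,
                conf=float(round(conf, 3)),
                start=u.start + (i * dur) // n,
                end=u.start + ((i + 1) * dur) // n,
            )
            for i, (tok, conf) in enumerate(kept)
        ]
        surviving.append((u, words))

    segments: list[AsrSegment] = []
    group: list[tuple[RefUtterance, list[Word]]] = []

    def flush():
        if not group:
            return
        words = tuple(w for _, ws in group for w in ws)
        text = " ".join(" ".join(w.token for w in ws) + "." for _, ws in group)
        is_cds = group[0][0].cds_label != "non_cds"
        loud = rng.uniform(8, 16) if is_cds else rng.uniform(2, 8)
        segments.append(AsrSegment(
            start=words[0].start,
            end=words[-1].end,
            speaker_class=group[0][0].speaker_class,
            punctuated_text=text,
            words=words,
            loudness=float(round(loud, 3)),
        ))
        group.clear()

    for u, words in surviving:
        if group and (u.speaker_class != group[-1][0].speaker_class
                      or u.start - group[-1][0].end >= 1000):
            flush()
        group.append((u, words))
    flush()
    return segments
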