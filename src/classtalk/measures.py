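"""Child-directed-speech and interaction summary measures.

Five transcript measures per partner class and session:

* TNU — total number of utterances
* TNW — total number of words
* NDW — number of different words (distinct types over all utterances)
* MLU — mean length of utterance, TNW / TNU
* TTR — type-token ratio, NDW / TNW

and four interaction-track measures: frequency, median duration, standard
deviation of duration, and total duration of interactions (TDI).

Count measures are normed to a 10-minute recording (multiplied by
``10 / recording_minutes``) so children with unequal recording times are
comparable.  MLU and TTR are ratios of raw counts and are never normed;
durations are physical times and are never normed either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intervals import IntervalTrack

__all__ = [
    "CONTRACTIONS",
    "tokenize_utterance",
    "MeasureSet",
    "InteractionMeasures",
    "cds_measures",
    "interaction_measures",
]

# Fixed contraction table, applied before word counting so automatic
# transcripts are tokenized the same way as reference transcripts
# (e.g. "you're" counts as the two words "you are").
CONTRACTIONS: dict[str, tuple[str, ...]] = {
    "i'm": ("i", "am"),
    "you're": ("you", "are"),
    "we're": ("we", "are"),
    "they're": ("they", "are"),
    "it's": ("it", "is"),
    "that's": ("that", "is"),
    "what's": ("what", "is"),
    "he's": ("he", "is"),
    "she's": ("she", "is"),
    "there's": ("there", "is"),
    "here's": ("here", "is"),
    "who's": ("who", "is"),
    "let's": ("let", "us"),
    "don't": ("do", "not"),
    "doesn't": ("does", "not"),
    "didn't": ("did", "not"),
    "can't": ("can", "not"),
    "couldn't": ("could", "not"),
    "won't": ("will", "not"),
    "wouldn't": ("would", "not"),
    "shouldn't": ("should", "not"),
    "isn't": ("is", "not"),
    "aren't": ("are", "not"),
    "wasn't": ("was", "not"),
    "weren't": ("were", "not"),
    "haven't": ("have", "not"),
    "hasn't": ("has", "not"),
    "hadn't": ("had", "not"),
    "i'll": ("i", "will"),
    "you'll": ("you", "will"),
    "he'll": ("he", "will"),
    "she'll": ("she", "will"),
    "we'll": ("we", "will"),
    "they'll": ("they", "will"),
    "i've": ("i", "have"),
    "you've": ("you", "have"),
    "we've": ("we", "have"),
    "they've": ("they", "have"),
    "i'd": ("i", "would"),
    "you'd": ("you", "would"),
    "he'd": ("he", "would"),
    "she'd": ("she", "would"),
    "we'd": ("we", "would"),
    "they'd": ("they", "would"),
}

_STRIP = ".,!?;:\"'()[]-"


def tokenize_utterance(text: str) -> list[str]:
    """Normalize utterance text to a list of word tokens.

    Lowercases, strips surrounding punctuation, and expands contractions from
    the fixed table (``"You're going home."`` -> ``[you, are, going, home]``).
    Whitespace-only input yields an empty list.
    """
    tokens: list[str] = []
    for raw in text.lower().replace("’", "'").split():
        word = raw.strip(_STRIP)
        if not word:
            continue
        tokens.extend(CONTRACTIONS.get(word, (word,)))
    return tokens


@dataclass(frozen=True)
class MeasureSet:
    """The five CDS measures for one child and partner class."""

    tnu: float
    tnw: float
    ndw: float
    mlu: float | None
    ttr: float | None
    recording_minutes: float
    normed: bool


@dataclass(frozen=True)
class InteractionMeasures:
    """Interaction-track summaries for one child and partner class (durations in s)."""

    frequency: float
    median_dur_s: float | None
    sd_dur_s: float | None
    total_dur_s: float
    recording_minutes: float
    normed: bool


def cds_measures(
    token_lists, recording_minutes: float, norm: bool = True
) -> MeasureSet:
    """Measures over the utterances (token lists) of one partner class.

    MLU and TTR are always computed from raw counts; when ``norm`` is set the
    three count measures are scaled by ``10 / recording_minutes``.  With zero
    utterances the counts are 0 and MLU/TTR are ``None`` (undefined, never 0).
    """
    if recording_minutes <= 0:
        raise ValueError("recording_minutes must be positive")
    tokens = [list(t) for t in token_lists if len(list(t)) > 0]
    tnu = len(tokens)
    tnw = sum(len(t) for t in tokens)
    ndw = len({w for t in tokens for w in t})
    mlu = tnw / tnu if tnu else None
    ttr = ndw / tnw if tnw else None
    factor = 10.0 / recording_minutes if norm else 1.0
    return MeasureSet(
        tnu=tnu * factor,
        tnw=tnw * factor,
        ndw=ndw * factor,
        mlu=mlu,
        ttr=ttr,
        recording_minutes=recording_minutes,
        normed=norm,
    )


def interaction_measures(
    track: IntervalTrack, recording_minutes: float, norm: bool = True
) -> InteractionMeasures:
    """Frequency, median/SD of duration, and total duration of a track.

    Only the frequency (a count) is normed; durations are reported in
    seconds, un-normed.  An empty track has frequency 0, TDI 0, and undefined
    median/SD.
    """
    if recording_minutes <= 0:
        raise ValueError("recording_minutes must be positive")
    durs = track.durations_ms() / 1000.0
    factor = 10.0 / recording_minutes if norm else 1.0
    if durs.size == 0:
        return InteractionMeasures(0.0, None, None, 0.0, recording_minutes, norm)
    return InteractionMeasures(
        frequency=len(durs) * factor,
        median_dur_s=float(np.median(durs)),
        sd_dur_s=float(np.std(durs)),
        total_dur_s=float(durs.sum()),
        recording_minutes=recording_minutes,
        normed=norm,
    )
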