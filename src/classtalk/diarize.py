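"""Assignment of utterances to child-directed-speech classes.

CDS is operationalized as talk occurring *within* an interaction: an
utterance whose time span positively overlaps an adult-interaction interval
is adult-CDS; otherwise, overlap with a peer interval makes it peer-CDS;
otherwise it is non-CDS.  When an utterance overlaps both tracks the adult
takes precedence.  Overlap is strict — touching an interval endpoint under
the half-open convention is zero-length and does not count.

Assignment depends only on temporal overlap, not on who is speaking: an
utterance by a peer during an adult interaction is adult-CDS.  The focal
child's own speech is handled separately and partitioned by the partner
class it was directed to (same precedence); focal speech outside any
interaction is excluded from the measures.
"""

from __future__ import annotations

from .ingest import Utterance
from .intervals import IntervalTrack

__all__ = ["assign_utterances", "collect_focal_speech"]


def _label(u: Utterance, adult_track: IntervalTrack, peer_track: IntervalTrack) -> str:
    if adult_track.intersects(u.start, u.end):
        return "adult_cds"
    if peer_track.intersects(u.start, u.end):
        return "peer_cds"
    return "non_cds"


def assign_utterances(
    utterances: list[Utterance],
    adult_track: IntervalTrack,
    peer_track: IntervalTrack,
) -> list[Utterance]:
    """Label every non-focal utterance adult_cds / peer_cds / non_cds."""
    out = []
    for u in utterances:
        if u.speaker_class == "focal":
            raise ValueError("focal-child utterances go through collect_focal_speech")
        out.append(u.with_label(_label(u, adult_track, peer_track)))
    return out


def collect_focal_speech(
    utterances: list[Utterance],
    adult_track: IntervalTrack,
    peer_track: IntervalTrack,
) -> dict[str, list[Utterance]]:
    """Partition focal-child utterances by the partner class they intersect.

    Returns {"adult": [...], "peer": [...], "excluded": [...]}; excluded
    utterances fall outside every interaction and enter no measure.
    """
    out: dict[str, list[Utterance]] = {"adult": [], "peer": [], "excluded": []}
    for u in utterances:
        if u.speaker_class != "focal":
            raise ValueError("collect_focal_speech only accepts focal-child utterances")
        label = _label(u, adult_track, peer_track)
        key = {"adult_cds": "adult", "peer_cds": "peer", "non_cds": "excluded"}[label]
        out[key].append(u.with_label(label if label != "non_cds" else "unassigned"))
    return out
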