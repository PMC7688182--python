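"""Parsing and harmonization of scene-featurization and ASR records.

This is the boundary between external featurizers (face detection, face
search, automatic speech recognition) and the pipeline: face detections are
joined to identity matches, non-teacher adults (research staff) are removed,
one representative face per class is kept per frame, and ASR segments are
split into punctuation-bounded utterances with normalized tokens.

Timestamps are integer milliseconds; bounding boxes are normalized to the
frame, ``(x, y, w, h)`` with all coordinates in [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .measures import tokenize_utterance

log = logging.getLogger(__name__)

__all__ = [
    "FaceDetection",
    "FaceMatch",
    "LabeledFace",
    "Word",
    "AsrSegment",
    "Utterance",
    "bbox_iou",
    "parse_face_detections",
    "parse_face_matches",
    "resolve_identities",
    "select_representative_faces",
    "segment_utterances",
    "compute_segment_loudness",
]

SENTENCE_FINAL = (".", "?", "!")


@dataclass(frozen=True)
class FaceDetection:
    """One face-detector hit: box, head pose, mouth/eyes-open confidences."""

    t: int  # ms
    bbox: tuple[float, float, float, float]  # x, y, w, h, normalized
    yaw: float
    roll: float
    pitch: float
    mouth_open_conf: float  # [0, 100]
    eyes_open_conf: float  # [0, 100]

    @property
    def area(self) -> float:
        return self.bbox[2] * self.bbox[3]


@dataclass(frozen=True)
class FaceMatch:
    """One face-recognition hit against the enrolled face collection."""

    t: int  # ms
    face_id: str
    similarity: float  # [0, 100]
    bbox: tuple[float, float, float, float]


@dataclass(frozen=True)
class LabeledFace:
    """A detection resolved to a participant class ("adult" or "peer")."""

    t: int
    participant_class: str
    area: float
    yaw: float
    roll: float
    pitch: float
    mouth_open_conf: float
    eyes_open_conf: float


@dataclass(frozen=True)
class Word:
    token: str
    conf: float  # [0, 1]
    start: int  # ms
    end: int  # ms


@dataclass(frozen=True)
class AsrSegment:
    """One diarized speech segment from the transcription service."""

    start: int  # ms
    end: int  # ms
    speaker_class: str  # adult | peer | focal
    punctuated_text: str
    words: tuple[Word, ...]
    loudness: float | None = None

    @property
    def mean_confidence(self) -> float:
        return float(np.mean([w.conf for w in self.words])) if self.words else 0.0


@dataclass(frozen=True)
class Utterance:
    """A punctuation-bounded utterance with normalized tokens."""

    start: int  # ms
    end: int  # ms
    tokens: tuple[str, ...]
    speaker_class: str
    mean_confidence: float
    loudness: float = 0.0
    cds_label: str = "unassigned"  # adult_cds | peer_cds | non_cds | unassigned

    def with_label(self, label: str) -> "Utterance":
        return replace(self, cds_label=label)


def bbox_iou(a, b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _get_bbox(rec) -> tuple[float, float, float, float]:
    b = rec["bbox"]
    bbox = (float(b["x"]), float(b["y"]), float(b["w"]), float(b["h"]))
    x, y, w, h = bbox
    if not (0 <= x and 0 <= y and x + w <= 1 + 1e-9 and y + h <= 1 + 1e-9 and w > 0 and h > 0):
        raise ValueError(f"bbox out of frame: {bbox}")
    return bbox


def parse_face_detections(lines) -> tuple[list[FaceDetection], int]:
    """Parse face-detection JSONL; malformed records are counted and skipped.

    ``lines`` is an iterable of JSON strings (one object per line).  Returns
    the detections sorted by time and the number of skipped records.  An
    empty input yields an empty list (with a warning, not an error).
    """
    out: list[FaceDetection] = []
    skipped = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            pose = rec["pose"]
            det = FaceDetection(
                t=int(rec["t_ms"]),
                bbox=_get_bbox(rec),
                yaw=float(pose["yaw"]),
                roll=float(pose["roll"]),
                pitch=float(pose["pitch"]),
                mouth_open_conf=float(rec["mouth_open_conf"]),
                eyes_open_conf=float(rec["eyes_open_conf"]),
            )
            if det.t < 0:
                raise ValueError("negative timestamp")
            out.append(det)
        except (KeyError, TypeError, ValueError) as exc:
            skipped += 1
            log.warning("skipping malformed face record at line %d: %s", i + 1, exc)
    if not out:
        log.warning("no face detections parsed")
    out.sort(key=lambda d: d.t)
    return out, skipped


def parse_face_matches(lines) -> tuple[list[FaceMatch], int]:
    """Parse face-match JSONL; same skip semantics as detections."""
    out: list[FaceMatch] = []
    skipped = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            m = FaceMatch(
                t=int(rec["t_ms"]),
                face_id=str(rec["face_id"]),
                similarity=float(rec["similarity"]),
                bbox=_get_bbox(rec),
            )
            if not 0 <= m.similarity <= 100:
                raise ValueError("similarity out of range")
            out.append(m)
        except (KeyError, TypeError, ValueError) as exc:
            skipped += 1
            log.warning("skipping malformed match record at line %d: %s", i + 1, exc)
    out.sort(key=lambda m: m.t)
    return out, skipped


def resolve_identities(
    detections: list[FaceDetection],
    matches: list[FaceMatch],
    identity_map: dict[str, str],
    sim_threshold: float = 92.0,
    t_tol_ms: int = 250,
    iou_min: float = 0.5,
    unmatched_class: str = "peer",
) -> list[LabeledFace]:
    """Join detections to recognition matches and assign participant classes.

    A detection takes a match's class when the timestamps agree within
    ``t_tol_ms``, the boxes overlap with IoU >= ``iou_min``, and the match
    similarity is at least ``sim_threshold`` (the recognition service is only
    trusted above 92% similarity).  Detections resolved to ``other_adult``
    (research staff and other non-teacher adults) are removed entirely.
    Unmatched detections default to ``unmatched_class`` — in a classroom the
    overwhelming majority of unenrolled faces are children.
    """
    out: list[LabeledFace] = []
    for det in detections:
        best = None
        best_key = None
        for m in matches:
            if abs(m.t - det.t) > t_tol_ms or m.similarity < sim_threshold:
                continue
            iou = bbox_iou(det.bbox, m.bbox)
            if iou < iou_min:
                continue
            key = (m.similarity, -abs(m.t - det.t), iou)
            if best_key is None or key > best_key:
                best, best_key = m, key
        if best is not None:
            cls = identity_map.get(best.face_id, unmatched_class)
            if cls == "other_adult":
                continue  # remove non-teacher adults from the scene
        else:
            cls = unmatched_class
        out.append(
            LabeledFace(
                t=det.t,
                participant_class=cls,
                area=det.area,
                yaw=det.yaw,
                roll=det.roll,
                pitch=det.pitch,
                mouth_open_conf=det.mouth_open_conf,
                eyes_open_conf=det.eyes_open_conf,
            )
        )
    return out


def select_representative_faces(
    faces_at_frame: list[LabeledFace],
) -> dict[str, LabeledFace]:
    """Pick, per class, the face with the largest bounding-box area.

    Box area is the proxy for proximity to the focal child: the nearest
    (largest) adult and peer face represent the frame.  Ties keep the
    earliest face in input order.  Returns a dict with keys among
    {"adult", "peer"}; an absent class is simply missing.
    """
    best: dict[str, LabeledFace] = {}
    for face in faces_at_frame:
        cur = best.get(face.participant_class)
        if cur is None or face.area > cur.area:
            best[face.participant_class] = face
    return best


def segment_utterances(segments: list[AsrSegment]) -> list[Utterance]:
    """Split ASR segments into utterances at sentence-final punctuation.

    The punctuated text tokens are aligned one-to-one with the timed words;
    a split happens after any text token ending in ``. ? !`` (commas never
    split).  Each utterance spans its first word's start to its last word's
    end; tokens are normalized with :func:`tokenize_utterance`.
    """
    out: list[Utterance] = []
    for seg in segments:
        if seg.words and not seg.punctuated_text.strip():
            raise ValueError("segment has words but no punctuated text")
        if not seg.words:
            continue
        text_tokens = seg.punctuated_text.split()
        if len(text_tokens) != len(seg.words):
            # alignment unavailable: treat the whole segment as one utterance
            log.warning(
                "text/word count mismatch (%d vs %d); keeping segment whole",
                len(text_tokens),
                len(seg.words),
            )
            groups = [list(range(len(seg.words)))]
        else:
            groups = []
            cur: list[int] = []
            for i, tok in enumerate(text_tokens):
                cur.append(i)
                if tok.endswith(SENTENCE_FINAL):
                    groups.append(cur)
                    cur = []
            if cur:
                groups.append(cur)
        aligned = len(text_tokens) == len(seg.words)
        for grp in groups:
            words = [seg.words[i] for i in grp]
            text = " ".join(text_tokens[i] for i in grp) if aligned else seg.punctuated_text
            tokens = tuple(tokenize_utterance(text))
            if not tokens:
                continue
            out.append(
                Utterance(
                    start=words[0].start,
                    end=words[-1].end,
                    tokens=tokens,
                    speaker_class=seg.speaker_class,
                    mean_confidence=float(np.mean([w.conf for w in words])),
                    loudness=seg.loudness if seg.loudness is not None else 0.0,
                )
            )
    return out


def compute_segment_loudness(segment: AsrSegment, amplitudes=None) -> float:
    """Loudness for one segment: precomputed channel, else an energy proxy.

    When the segment carries a precomputed loudness value it is returned
    unchanged.  Otherwise a documented proxy is applied to raw sample
    amplitudes: mean squared amplitude mapped through a fixed monotone power
    law (exponent 0.3, a Stevens-type compression).  Loudness is only ever a
    relative acoustic-proximity proxy downstream, so any fixed monotone
    transform serves.
    """
    if segment.loudness is not None:
        return segment.loudness
    if amplitudes is None:
        raise ValueError(
            "no loudness available: segment has no precomputed loudness channel "
            "and no sample amplitudes were given"
        )
    a = np.asarray(amplitudes, dtype=float)
    return float(np.mean(a * a) ** 0.3)
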