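"""On-disk schemas and round-trip readers/writers.

One documented format per artifact, all plain text, UTF-8, timestamps in
integer ms, intervals half-open:

* face detections — JSONL, one object per detection:
  ``{"t_ms", "bbox": {"x","y","w","h"}, "pose": {"yaw","roll","pitch"},
  "mouth_open_conf", "eyes_open_conf"}``
* face matches — JSONL: ``{"t_ms", "face_id", "similarity", "bbox": {...}}``
* identity map — CSV ``face_id,participant_id,class``
* ASR — JSON ``{"segments": [{"start_ms","end_ms","speaker_class",
  "punctuated_text","loudness","words":[{"w","conf","start_ms","end_ms"}]}]}``
* interaction intervals — CSV ``child_id,partner,onset_ms,offset_ms``
* reference transcript — TSV ``speaker_code<TAB>onset_ms<TAB>offset_ms<TAB>text``
* measures — CSV ``child_id,partner,TNU,TNW,NDW,MLU,TTR,recording_min,normed``

Floats are canonicalized to at most 6 decimals on write, so
``write(read(path))`` reproduces a written file byte-identically.  The
strict readers here raise on the first malformed record, naming its line;
the lenient skip-and-count parsers for featurizer output live in
:mod:`classtalk.ingest`.
"""

from __future__ import annotations

import json
from pathlib import Path

from .ingest import AsrSegment, FaceDetection, FaceMatch, Word
from .intervals import IntervalTrack
from .measures import MeasureSet

__all__ = [
    "read_face_jsonl", "write_face_jsonl",
    "read_matches_jsonl", "write_matches_jsonl",
    "read_identity_csv", "write_identity_csv",
    "read_asr_json", "write_asr_json",
    "read_intervals_csv", "write_intervals_csv",
    "read_transcript_tsv", "write_transcript_tsv",
    "write_measures_csv",
]


def _num(x: float) -> float | int:
    """Canonical float: at most 6 decimals, integers stay integers."""
    if isinstance(x, bool):
        return x
    r = round(float(x), 6)
    return int(r) if r == int(r) else r


def _bbox_obj(b):
    return {"x": _num(b[0]), "y": _num(b[1]), "w": _num(b[2]), "h": _num(b[3])}


def _bbox_tuple(obj, where):
    try:
        return (float(obj["x"]), float(obj["y"]), float(obj["w"]), float(obj["h"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{where}: bad bbox object") from exc


# ------------------------------------------------------------------ face JSONL


def write_face_jsonl(path, detections: list[FaceDetection]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in detections:
            fh.write(json.dumps({
                "t_ms": int(d.t),
                "bbox": _bbox_obj(d.bbox),
                "pose": {"yaw": _num(d.yaw), "roll": _num(d.roll), "pitch": _num(d.pitch)},
                "mouth_open_conf": _num(d.mouth_open_conf),
                "eyes_open_conf": _num(d.eyes_open_conf),
            }) + "\n")


def read_face_jsonl(path) -> list[FaceDetection]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                pose = rec["pose"]
                out.append(FaceDetection(
                    t=int(rec["t_ms"]),
                    bbox=_bbox_tuple(rec["bbox"], f"line {i}"),
                    yaw=float(pose["yaw"]), roll=float(pose["roll"]),
                    pitch=float(pose["pitch"]),
                    mouth_open_conf=float(rec["mouth_open_conf"]),
                    eyes_open_conf=float(rec["eyes_open_conf"]),
                ))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed face record at line {i}: {exc}") from exc
    return out


# --------------------------------------------------------------- matches JSONL


def write_matches_jsonl(path, matches: list[FaceMatch]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in matches:
            fh.write(json.dumps({
                "t_ms": int(m.t),
                "face_id": m.face_id,
                "similarity": _num(m.similarity),
                "bbox": _bbox_obj(m.bbox),
            }) + "\n")


def read_matches_jsonl(path) -> list[FaceMatch]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out.append(FaceMatch(
                    t=int(rec["t_ms"]),
                    face_id=str(rec["face_id"]),
                    similarity=float(rec["similarity"]),
                    bbox=_bbox_tuple(rec["bbox"], f"line {i}"),
                ))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed match record at line {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------- identity CSV


def write_identity_csv(path, identity_map: dict[str, str]) -> None:
    """identity_map: face_id -> class (participant_id mirrors face_id here)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("face_id,participant_id,class\n")
        for face_id, cls in identity_map.items():
            fh.write(f"{face_id},{face_id},{cls}\n")


def read_identity_csv(path) -> dict[str, str]:
    out = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != ["face_id", "participant_id", "class"]:
            raise ValueError(f"{path}: unexpected identity-map header {header}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed identity row at line {i}")
            out[parts[0]] = parts[2]
    return out


# -------------------------------------------------------------------- ASR JSON


def write_asr_json(path, segments: list[AsrSegment]) -> None:
    doc = {"segments": [
        {
            "start_ms": int(s.start),
            "end_ms": int(s.end),
            "speaker_class": s.speaker_class,
            "punctuated_text": s.punctuated_text,
            "loudness": _num(s.loudness) if s.loudness is not None else None,
            "words": [
                {"w": w.token, "conf": _num(w.conf),
                 "start_ms": int(w.start), "end_ms": int(w.end)}
                for w in s.words
            ],
        }
        for s in segments
    ]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_asr_json(path) -> list[AsrSegment]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    out = []
    for i, s in enumerate(doc["segments"]):
        try:
            out.append(AsrSegment(
                start=int(s["start_ms"]),
                end=int(s["end_ms"]),
                speaker_class=str(s["speaker_class"]),
                punctuated_text=str(s["punctuated_text"]),
                loudness=None if s["loudness"] is None else float(s["loudness"]),
                words=tuple(
                    Word(token=str(w["w"]), conf=float(w["conf"]),
                         start=int(w["start_ms"]), end=int(w["end_ms"]))
                    for w in s["words"]
                ),
            ))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed ASR segment #{i}: {exc}") from exc
    return out


# --------------------------------------------------------------- intervals CSV


def write_intervals_csv(path, tracks: dict[str, dict[str, IntervalTrack]]) -> None:
    """tracks: child_id -> partner -> IntervalTrack."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child_id,partner,onset_ms,offset_ms\n")
        for child_id in sorted(tracks):
            for partner in sorted(tracks[child_id]):
                for on, off in tracks[child_id][partner].intervals:
                    fh.write(f"{child_id},{partner},{on},{off}\n")


def read_intervals_csv(path, source: str = "reference") -> dict[str, dict[str, IntervalTrack]]:
    rows: dict[str, dict[str, list]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != ["child_id", "partner", "onset_ms", "offset_ms"]:
            raise ValueError(f"{path}: unexpected intervals header {header}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed interval row at line {i}")
            child, partner, on, off = parts
            rows.setdefault(child, {}).setdefault(partner, []).append((int(on), int(off)))
    return {
        child: {
            partner: IntervalTrack.from_intervals(partner, ivs, source=source)
            for partner, ivs in partners.items()
        }
        for child, partners in rows.items()
    }


# -------------------------------------------------------------- transcript TSV


def write_transcript_tsv(path, utterances) -> None:
    """utterances: iterable with .speaker_class, .start, .end, .words (tokens)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u in utterances:
            text = " ".join(u.words)
            fh.write(f"{u.speaker_class}\t{int(u.start)}\t{int(u.end)}\t{text}\n")


def read_transcript_tsv(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed transcript row at line {i}")
            out.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return out


# ---------------------------------------------------------------- measures CSV


def write_measures_csv(path, rows: list[tuple[str, str, MeasureSet]]) -> None:
    """rows: (child_id, partner, MeasureSet)."""

    def fmt(v):
        return "" if v is None else f"{v:.6g}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child_id,partner,TNU,TNW,NDW,MLU,TTR,recording_min,normed\n")
        for child_id, partner, m in rows:
            fh.write(
                f"{child_id},{partner},{fmt(m.tnu)},{fmt(m.tnw)},{fmt(m.ndw)},"
                f"{fmt(m.mlu)},{fmt(m.ttr)},{fmt(m.recording_minutes)},{int(m.normed)}\n"
            )
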