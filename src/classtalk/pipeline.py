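"""End-to-end orchestration: sessions -> detectors -> tracks -> measures.

Ties the stages together the way a validation study runs them: featurize
each child's session, leave-one-subject-out train/apply the adult and peer
interaction detectors, map utterances onto the predicted tracks, compute
the five CDS measures per partner class (plus the focal child's own speech
and total interaction durations), and score raw and OLP-calibrated
automatic measures against the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diarize, evaluate, features, ingest, measures
from .detector import DetectorSpec, loso_run
from .intervals import IntervalTrack
from .simulate import SyntheticSession

log = logging.getLogger(__name__)

__all__ = [
    "SessionInputs",
    "preprocess_session",
    "session_inputs",
    "utterances_from_reference",
    "class_measures",
    "flatten_measures",
    "MEASURE_KEYS",
    "run_loso_experiment",
    "detector_table",
    "measures_table",
]

SPEAKERS = ("adult", "peer", "focal")
CDS_NAMES = ("TNU", "TNW", "NDW", "MLU", "TTR")
MEASURE_KEYS = [f"{spk}_{m}" for spk in SPEAKERS for m in CDS_NAMES] + [
    "adult_TDI",
    "peer_TDI",
]


@dataclass
class SessionInputs:
    """Everything one child's session contributes to the experiment."""

    child_id: str
    session_ms: int
    series: features.FeatureSeries  # preprocessed, unnormalized
    utterances: list[ingest.Utterance]  # from ASR output
    reference_utterances: list[ingest.Utterance]  # from reference transcript
    truth_adult: IntervalTrack
    truth_peer: IntervalTrack


def preprocess_session(
    detections,
    matches,
    identity_map,
    asr_segments,
    session_ms: int,
    child_id: str = "",
    infill_window_bins: int = 5,
    clip_q: float = 0.99,
):
    """Featurize one session: identity resolution, utterance segmentation,
    rasterize -> infill -> clip.  Normalization happens per training fold,
    later.  Returns (FeatureSeries, utterances)."""
    faces = ingest.resolve_identities(detections, matches, identity_map)
    utts = ingest.segment_utterances(asr_segments)
    series = features.rasterize(faces, utts, session_ms, child_id=child_id)
    series = features.infill_moving_average(series, infill_window_bins)
    series = features.clip_outliers(series, clip_q)
    return series, utts


def utterances_from_reference(session: SyntheticSession) -> list[ingest.Utterance]:
    """Reference transcript rows as normalized utterances (perfect transcription)."""
    out = []
    for u in session.reference_utterances:
        tokens = tuple(measures.tokenize_utterance(" ".join(u.words)))
        if not tokens:
            continue
        out.append(
            ingest.Utterance(
                start=u.start, end=u.end, tokens=tokens,
                speaker_class=u.speaker_class, mean_confidence=1.0,
            )
        )
    return out


def session_inputs(session: SyntheticSession) -> SessionInputs:
    series, utts = preprocess_session(
        session.face_detections,
        session.face_matches,
        session.identity_map,
        session.asr_segments,
        session.session_ms,
        child_id=session.child_id,
    )
    return SessionInputs(
        child_id=session.child_id,
        session_ms=session.session_ms,
        series=series,
        utterances=utts,
        reference_utterances=utterances_from_reference(session),
        truth_adult=session.truth_adult,
        truth_peer=session.truth_peer,
    )


def class_measures(
    utterances: list[ingest.Utterance],
    adult_track: IntervalTrack,
    peer_track: IntervalTrack,
    recording_minutes: float,
) -> dict:
    """Per-class measure sets given interaction tracks (reference or predicted)."""
    non_focal = [u for u in utterances if u.speaker_class != "focal"]
    focal = [u for u in utterances if u.speaker_class == "focal"]
    labeled = diarize.assign_utterances(non_focal, adult_track, peer_track)
    focal_parts = diarize.collect_focal_speech(focal, adult_track, peer_track)
    by_class = {
        "adult": [u.tokens for u in labeled if u.cds_label == "adult_cds"],
        "peer": [u.tokens for u in labeled if u.cds_label == "peer_cds"],
        "focal": [u.tokens for u in focal_parts["adult"] + focal_parts["peer"]],
    }
    out = {
        spk: measures.cds_measures(toks, recording_minutes) for spk, toks in by_class.items()
    }
    out["adult_interaction"] = measures.interaction_measures(adult_track, recording_minutes)
    out["peer_interaction"] = measures.interaction_measures(peer_track, recording_minutes)
    return out


def flatten_measures(class_sets: dict) -> dict[str, float | None]:
    """Flat {measure_key: value} dict in the MEASURE_KEYS layout."""
    flat: dict[str, float | None] = {}
    for spk in SPEAKERS:
        m = class_sets[spk]
        flat[f"{spk}_TNU"] = m.tnu
        flat[f"{spk}_TNW"] = m.tnw
        flat[f"{spk}_NDW"] = m.ndw
        flat[f"{spk}_MLU"] = m.mlu
        flat[f"{spk}_TTR"] = m.ttr
    flat["adult_TDI"] = class_sets["adult_interaction"].total_dur_s
    flat["peer_TDI"] = class_sets["peer_interaction"].total_dur_s
    return flat


def run_loso_experiment(
    inputs: list[SessionInputs],
    adult_spec: DetectorSpec,
    peer_spec: DetectorSpec,
    min_dur_ms: int = 1000,
) -> dict:
    """The full leave-one-subject-out validation.

    Returns a dict with per-partner detection results ("detection"), the
    per-child raw/reference measure vectors, and the calibrated measure
    evaluation ("measure_eval").
    """
    detection = {}
    for spec, truth_attr in ((adult_spec, "truth_adult"), (peer_spec, "truth_peer")):
        cohort = [(si.child_id, si.series, getattr(si, truth_attr)) for si in inputs]
        detection[spec.partner_class] = loso_run(cohort, spec, min_dur_ms=min_dur_ms)

    raw: dict[str, dict[str, float]] = {k: {} for k in MEASURE_KEYS}
    ref: dict[str, dict[str, float]] = {k: {} for k in MEASURE_KEYS}
    for si in inputs:
        minutes = si.session_ms / 60000.0
        pred_adult = detection["adult"][si.child_id]["track"]
        pred_peer = detection["peer"][si.child_id]["track"]
        raw_flat = flatten_measures(
            class_measures(si.utterances, pred_adult, pred_peer, minutes)
        )
        ref_flat = flatten_measures(
            class_measures(si.reference_utterances, si.truth_adult, si.truth_peer, minutes)
        )
        for k in MEASURE_KEYS:
            if raw_flat[k] is not None:
                raw[k][si.child_id] = raw_flat[k]
            if ref_flat[k] is not None:
                ref[k][si.child_id] = ref_flat[k]

    measure_eval = evaluate.loso_measure_eval(raw, ref, measures=MEASURE_KEYS)
    return {"detection": detection, "raw": raw, "ref": ref, "measure_eval": measure_eval}


def detector_table(detection: dict) -> pd.DataFrame:
    """Mean sample-level metrics over held-out children, one row per detector."""
    rows = []
    for partner, folds in detection.items():
        metrics = [f["metrics"] for f in folds.values()]
        row = {"partner": partner, "n_children": len(metrics)}
        for name in ("accuracy", "precision", "recall", "f1"):
            vals = [getattr(m, name) for m in metrics if getattr(m, name) is not None]
            row[name] = float(np.mean(vals)) if vals else None
        rows.append(row)
    return pd.DataFrame(rows)


def measures_table(measure_eval: dict) -> pd.DataFrame:
    """Tidy speaker x measure x adaptation table of mARE and r."""
    rows = []
    for key, res in measure_eval.items():
        spk, name = key.split("_", 1)
        for kind in ("raw", "adapted"):
            am = res[kind]
            rows.append({
                "speaker": spk,
                "measure": name,
                "adaptation": kind,
                "mARE": am.mare,
                "MRE": am.mre,
                "r": am.r,
                "n_children": len(am.are_per_child),
            })
    return pd.DataFrame(rows)
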