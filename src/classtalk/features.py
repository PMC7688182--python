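"""Fixed-rate feature series for the interaction detector.

Labeled faces and utterances are rasterized onto a 250 ms grid into a
15-channel matrix: six facial channels for the representative adult face
(box area, yaw, roll, pitch, mouth-open and eyes-open confidence), the same
six for the representative peer face, then speech activity (0/1), segment
word confidence, and segment loudness.

Preprocessing order is fixed: rasterize -> infill -> clip -> normalize.
Face channels are gap-marked (NaN) wherever no face of that class was
detected; infilling repairs short gaps (occlusion dropouts and the 500 ms
native detector rate) with a centered moving average and fills long
absences with 0, the no-face baseline.  Per-channel upper-tail outliers are
clipped at the 99th percentile, and channels are z-scored with statistics
fitted on training sessions only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .ingest import LabeledFace, Utterance, select_representative_faces

log = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "FACE_FEATURES",
    "FeatureSeries",
    "NormStats",
    "rasterize",
    "infill_moving_average",
    "clip_outliers",
    "fit_normalize",
    "apply_normalize",
]

FACE_FEATURES = ("area", "yaw", "roll", "pitch", "mouth_open_conf", "eyes_open_conf")
CHANNELS: tuple[str, ...] = (
    tuple(f"adult_{f}" for f in FACE_FEATURES)
    + tuple(f"peer_{f}" for f in FACE_FEATURES)
    + ("speech_active", "word_conf", "loudness")
)
BOOLEAN_CHANNELS = frozenset({"speech_active"})


@dataclass(frozen=True)
class FeatureSeries:
    """T x 15 channel matrix at 250 ms resolution for one session."""

    child_id: str
    session_ms: int
    channels: np.ndarray  # (T, len(CHANNELS)), NaN marks face gaps pre-infill
    presence: dict[str, np.ndarray]  # per face class, (T,) bool
    dt_ms: int = 250

    @property
    def n_bins(self) -> int:
        return self.channels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[:, CHANNELS.index(name)]

    def with_channels(self, channels: np.ndarray) -> "FeatureSeries":
        return replace(self, channels=channels)


@dataclass(frozen=True)
class NormStats:
    """Per-channel center/scale, fitted on training sessions only."""

    center: np.ndarray
    scale: np.ndarray


def rasterize(
    faces: list[LabeledFace],
    utterances: list[Utterance],
    session_ms: int,
    child_id: str = "",
    dt_ms: int = 250,
    native_ms: int = 500,
) -> FeatureSeries:
    """Build the gapped (pre-infill) feature series.

    Each face frame covers the bins of its native sample period
    ``[t, t + native_ms)``; per frame and class only the representative
    (largest-box) face contributes.  Bins never covered by a face of a class
    carry NaN gap markers in that class's six channels.  ``speech_active``
    is 1 on bins with strictly positive overlap with any utterance; word
    confidence and loudness broadcast the covering utterance's values over
    those bins (the utterance with the largest overlap wins a contested bin)
    and are 0 during silence.
    """
    if session_ms <= 0:
        raise ValueError("session_ms must be positive")
    n_bins = -(-session_ms // dt_ms)
    X = np.zeros((n_bins, len(CHANNELS)))
    X[:, :12] = np.nan
    presence = {
        "adult": np.zeros(n_bins, dtype=bool),
        "peer": np.zeros(n_bins, dtype=bool),
    }

    by_frame: dict[int, list[LabeledFace]] = {}
    for f in faces:
        by_frame.setdefault(f.t, []).append(f)
    offsets = {"adult": 0, "peer": 6}
    for t, frame in sorted(by_frame.items()):
        reps = select_representative_faces(frame)
        lo = max(0, t // dt_ms)
        hi = min(n_bins, -(-(t + native_ms) // dt_ms))
        if hi <= lo:
            continue
        for cls, face in reps.items():
            if cls not in offsets:
                continue
            j = offsets[cls]
            vals = (face.area, face.yaw, face.roll, face.pitch,
                    face.mouth_open_conf, face.eyes_open_conf)
            X[lo:hi, j : j + 6] = vals
            presence[cls][lo:hi] = True

    overlap = np.zeros(n_bins)
    for u in utterances:
        lo = max(0, u.start // dt_ms)
        hi = min(n_bins, -(-u.end // dt_ms))
        for b in range(lo, hi):
            ov = min(u.end, (b + 1) * dt_ms) - max(u.start, b * dt_ms)
            if ov <= 0:
                continue
            X[b, 12] = 1.0
            if ov > overlap[b]:
                overlap[b] = ov
                X[b, 13] = u.mean_confidence
                X[b, 14] = u.loudness
    return FeatureSeries(child_id=child_id, session_ms=session_ms, channels=X,
                         presence=presence, dt_ms=dt_ms)


def infill_moving_average(series: FeatureSeries, window_bins: int = 5) -> FeatureSeries:
    """Repair face-channel gaps; no NaN remains afterwards.

    A gap bin takes the mean of the *observed* (originally non-gap) values
    inside a centered window of ``window_bins`` bins — this restores the
    250 ms rate from the 500 ms native face rate and bridges brief occlusion
    dropouts.  Gap bins with no observed neighbor in the window (long
    absences: no face of that class nearby) are filled with 0, the no-face
    baseline, so face presence remains encoded by the channel itself.  An
    all-gap channel is filled with 0 with a warning.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 1")
    X = series.channels.copy()
    kernel = np.ones(window_bins)
    for j, name in enumerate(CHANNELS):
        col = X[:, j]
        gaps = np.isnan(col)
        if not gaps.any():
            continue
        if gaps.all():
            log.warning("channel %s is all-gap; filling with 0", name)
            X[:, j] = 0.0
            continue
        obs = (~gaps).astype(float)
        sums = np.convolve(np.nan_to_num(col), kernel, mode="same")
        counts = np.convolve(obs, kernel, mode="same")
        fill = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        col[gaps] = fill[gaps]
    return series.with_channels(X)


def clip_outliers(series: FeatureSeries, q: float = 0.99) -> FeatureSeries:
    """Clip each channel's upper tail at its q-quantile (Boolean channels untouched)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    X = series.channels.copy()
    for j, name in enumerate(CHANNELS):
        if name in BOOLEAN_CHANNELS:
            continue
        thr = np.nanquantile(X[:, j], q)
        X[:, j] = np.minimum(X[:, j], thr)
    return series.with_channels(X)


def fit_normalize(training: list[FeatureSeries]) -> NormStats:
    """Per-channel mean/SD pooled over the training sessions.

    (Near-)constant channels pass through unchanged (center 0, scale 1).
    Applying the stats to held-out sessions, never refitting on them, keeps
    cross-validation leakage-free.
    """
    if not training:
        raise ValueError("training list is empty")
    pooled = np.concatenate([s.channels for s in training], axis=0)
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0)
    constant = scale < 1e-12
    center[constant] = 0.0
    scale[constant] = 1.0
    return NormStats(center=center, scale=scale)


def apply_normalize(series: FeatureSeries, stats: NormStats) -> FeatureSeries:
    return series.with_channels((series.channels - stats.center) / stats.scale)
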