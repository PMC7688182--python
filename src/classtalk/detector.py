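"""Interaction detectors: bidirectional LSTM sequence classifiers.

One detector per partner class (adult or peer), trained on whole classroom
sessions to label every 250 ms sample as interaction / not-interaction.
The *full* feature set feeds all 15 channels (12 facial + 3 audio); the
*reduced* set feeds only the partner class's face-box area (the proximity
proxy) and speech activity, emulating what a non-invasive proximity sensor
could provide.

Predicted per-bin labels are run-length encoded into interval tracks and
smoothed: gaps shorter than one second are merged, then intervals shorter
than one second are deleted — momentary flickers of either kind are not
plausible interaction boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._lstm import BiLSTM
from .features import CHANNELS, FeatureSeries, NormStats, apply_normalize, fit_normalize
from .intervals import IntervalTrack, intervals_from_mask, rasterize_intervals

log = logging.getLogger(__name__)

__all__ = [
    "DetectorSpec",
    "InteractionDetector",
    "build_detector",
    "train_detector",
    "predict_track",
    "smooth_track",
    "loso_run",
]


@dataclass(frozen=True)
class DetectorSpec:
    """Architecture and training settings for one interaction detector."""

    partner_class: str  # "adult" | "peer"
    feature_set: str = "full"  # "full" (15 channels) | "reduced" (area + speech)
    hidden_units: int = 200
    epochs: int = 30
    seed: int = 0
    learning_rate: float = 0.05
    window_bins: int | None = 240  # None: one whole session per sequence
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.partner_class not in ("adult", "peer"):
            raise ValueError(f"unknown partner_class {self.partner_class!r}")
        if self.feature_set not in ("full", "reduced"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.hidden_units <= 0 or self.epochs <= 0:
            raise ValueError("hidden_units and epochs must be positive")

    def feature_indices(self) -> list[int]:
        """Channel columns this detector consumes."""
        if self.feature_set == "full":
            return list(range(len(CHANNELS)))
        return [
            CHANNELS.index(f"{self.partner_class}_area"),
            CHANNELS.index("speech_active"),
        ]


@dataclass
class InteractionDetector:
    """A (possibly trained) detector: network + spec + its training-fold stats."""

    spec: DetectorSpec
    net: BiLSTM
    norm_stats: NormStats | None = None
    loss_history: list[float] = field(default_factory=list)


def build_detector(spec: DetectorSpec) -> InteractionDetector:
    """Seeded network with input width set by the feature set (15 full, 2 reduced)."""
    net = BiLSTM(
        n_features=len(spec.feature_indices()),
        hidden_units=spec.hidden_units,
        n_classes=2,
        seed=spec.seed,
    )
    return InteractionDetector(spec=spec, net=net)


def train_detector(
    model: InteractionDetector,
    sessions: list[tuple[FeatureSeries, np.ndarray]],
    norm_stats: NormStats | None = None,
) -> InteractionDetector:
    """Train on (normalized FeatureSeries, per-bin 0/1 labels) pairs.

    ``norm_stats`` (fitted on these training sessions) is stored on the
    model so held-out sessions are normalized identically at predict time.
    """
    idx = model.spec.feature_indices()
    seqs, labels = [], []
    for series, y in sessions:
        y = np.asarray(y, dtype=float)
        if series.n_bins != y.shape[0]:
            raise ValueError(
                f"label sequence length {y.shape[0]} != series length {series.n_bins}"
            )
        seqs.append(series.channels[:, idx])
        labels.append(y)
    model.loss_history = model.net.fit(
        seqs,
        labels,
        epochs=model.spec.epochs,
        lr=model.spec.learning_rate,
        window_bins=model.spec.window_bins,
        batch_size=model.spec.batch_size,
    )
    model.norm_stats = norm_stats
    return model


def predict_track(model: InteractionDetector, series: FeatureSeries) -> IntervalTrack:
    """Per-bin argmax labels, run-length encoded into an interval track (unsmoothed)."""
    idx = model.spec.feature_indices()
    if series.channels.shape[1] != len(CHANNELS):
        raise ValueError(
            f"series has {series.channels.shape[1]} channels, expected {len(CHANNELS)}"
        )
    mask = model.net.predict(series.channels[:, idx])
    return intervals_from_mask(
        mask, dt_ms=series.dt_ms, partner_class=model.spec.partner_class, source="predicted"
    )


def smooth_track(track: IntervalTrack, min_dur_ms: int = 1000) -> IntervalTrack:
    """Merge sub-second gaps, then delete sub-second intervals.

    After merging, all gaps are >= ``min_dur_ms``; deleting a short interval
    then concatenates two compliant gaps, so the result has no interval and
    no gap shorter than ``min_dur_ms`` and the operation is idempotent.
    """
    if min_dur_ms < 0:
        raise ValueError("min_dur_ms must be non-negative")
    merged: list[tuple[int, int]] = []
    for onset, offset in track.intervals:
        if merged and onset - merged[-1][1] < min_dur_ms:
            merged[-1] = (merged[-1][0], offset)
        else:
            merged.append((onset, offset))
    kept = tuple((a, b) for a, b in merged if b - a >= min_dur_ms)
    return IntervalTrack(track.partner_class, kept, track.source)


def loso_run(
    cohort: list[tuple[str, FeatureSeries, IntervalTrack]],
    spec: DetectorSpec,
    min_dur_ms: int = 1000,
) -> dict[str, dict]:
    """Leave-one-subject-out detection over a cohort.

    ``cohort`` holds per child: id, the preprocessed-but-unnormalized
    feature series (rasterized, infilled, clipped), and the reference track.
    For each fold, normalization statistics and the detector are fitted on
    the other children only, then applied to the held-out child.  Returns
    per child the smoothed predicted track, the trained fold model, and
    sample-level detection metrics.
    """
    from .evaluate import detection_metrics  # local import: avoid cycle

    if len(cohort) < 2:
        raise ValueError("LOSO needs at least 2 children")
    results: dict[str, dict] = {}
    for held_id, held_series, held_ref in cohort:
        train = [(cid, s, r) for cid, s, r in cohort if cid != held_id]
        stats = fit_normalize([s for _, s, _ in train])
        sessions = [
            (
                apply_normalize(s, stats),
                rasterize_intervals(r, s.session_ms, s.dt_ms).astype(float),
            )
            for _, s, r in train
        ]
        model = build_detector(spec)
        train_detector(model, sessions, norm_stats=stats)
        pred = predict_track(model, apply_normalize(held_series, stats))
        pred = smooth_track(pred, min_dur_ms)
        metrics = detection_metrics(pred, held_ref, held_series.session_ms, held_series.dt_ms)
        results[held_id] = {"track": pred, "metrics": metrics, "model": model}
        log.info("LOSO fold %s: f1=%s", held_id, metrics.f1)
    return results


def save_detector(path, model: InteractionDetector) -> None:
    """Checkpoint: network parameters, spec, and normalization stats in one npz."""
    import dataclasses
    import json as _json

    payload = {f"param_{k}": v for k, v in model.net.params.items()}
    payload["spec_json"] = np.array(_json.dumps(dataclasses.asdict(model.spec)))
    if model.norm_stats is not None:
        payload["norm_center"] = model.norm_stats.center
        payload["norm_scale"] = model.norm_stats.scale
    np.savez(path, **payload)


def load_detector(path) -> InteractionDetector:
    import json as _json

    with np.load(path, allow_pickle=False) as data:
        spec = DetectorSpec(**_json.loads(str(data["spec_json"])))
        model = build_detector(spec)
        for k in model.net.params:
            model.net.params[k] = data[f"param_{k}"]
        if "norm_center" in data:
            model.norm_stats = NormStats(
                center=data["norm_center"], scale=data["norm_scale"]
            )
    return model
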