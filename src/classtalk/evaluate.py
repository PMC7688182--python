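"""Validation metrics and calibration.

Detector agreement is scored at the 250 ms sample level: both tracks are
rasterized and accuracy / precision / recall / F1 are computed from the
per-bin confusion counts, reported as percentages.

Measure agreement uses the absolute relative error for child j,

    E_X,j = |X_r,j - X_p,j| / X_r,j * 100,

its median over children (mARE), the signed mean relative error
(MRE, negative = underestimation), and the Pearson correlation r between
the reference and predicted per-child vectors.

Raw automatic measures are calibrated with ordinary least products (OLP,
type II / geometric-mean) regression of reference on predicted values,
fitted strictly inside the cross-validation loop on training-fold children
and applied to the held-out child.  OLP treats both variables as noisy and
is symmetric: swapping x and y inverts the slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .intervals import IntervalTrack, rasterize_intervals

log = logging.getLogger(__name__)

__all__ = [
    "DetectionMetrics",
    "AgreementMetrics",
    "CalibrationModel",
    "detection_metrics",
    "relative_error",
    "summarize",
    "olp_fit",
    "olp_apply",
    "loso_measure_eval",
]


@dataclass(frozen=True)
class DetectionMetrics:
    """Sample-level confusion counts and derived percentages."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class AgreementMetrics:
    """Per-cohort agreement between reference and predicted measure vectors."""

    are_per_child: dict[str, float]
    mare: float | None  # median ARE, %
    mre: float | None  # signed mean relative error, %
    r: float | None  # Pearson correlation


@dataclass(frozen=True)
class CalibrationModel:
    """OLP slope/intercept mapping a raw predicted measure to reference scale."""

    measure: str
    slope: float
    intercept: float
    fold_id: str = ""


def detection_metrics(
    pred_track: IntervalTrack,
    ref_track: IntervalTrack,
    session_ms: int,
    dt_ms: int = 250,
) -> DetectionMetrics:
    """Confusion counts over all 250 ms bins of the session."""
    pred = rasterize_intervals(pred_track, session_ms, dt_ms).astype(bool)
    ref = rasterize_intervals(ref_track, session_ms, dt_ms).astype(bool)
    tp = int(np.sum(pred & ref))
    fp = int(np.sum(pred & ~ref))
    tn = int(np.sum(~pred & ~ref))
    fn = int(np.sum(~pred & ref))

    def pct(num, den):
        if den == 0:
            log.warning("zero denominator in detection metric")
            return None
        return 100.0 * num / den

    accuracy = pct(tp + tn, tp + fp + tn + fn)
    precision = pct(tp, tp + fp)
    recall = pct(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return DetectionMetrics(tp, fp, tn, fn, accuracy, precision, recall, f1)


def relative_error(x_ref: float, x_pred: float, signed: bool = False) -> float | None:
    """Percent relative error of a predicted measure against its reference.

    Unsigned: |ref - pred| / ref * 100.  Signed: (pred - ref) / ref * 100,
    so a negative value means underestimation.  A zero reference leaves the
    error undefined (None); callers exclude such children from summaries.
    """
    if x_ref == 0:
        log.warning("zero reference value; relative error undefined")
        return None
    if signed:
        return (x_pred - x_ref) / x_ref * 100.0
    return abs(x_ref - x_pred) / x_ref * 100.0


def summarize(
    are: dict[str, float],
    signed: dict[str, float],
    x_ref: dict[str, float],
    x_pred: dict[str, float],
) -> AgreementMetrics:
    """mARE, MRE and Pearson r over the per-child values (keyed by child id)."""
    mare = float(np.median(list(are.values()))) if are else None
    mre = float(np.mean(list(signed.values()))) if signed else None
    common = sorted(set(x_ref) & set(x_pred))
    r = None
    if len(common) >= 2:
        xr = np.array([x_ref[c] for c in common])
        xp = np.array([x_pred[c] for c in common])
        if np.std(xr) > 0 and np.std(xp) > 0:
            r = float(sps.pearsonr(xr, xp).statistic)
        else:
            log.warning("constant measure vector; correlation undefined")
    return AgreementMetrics(are_per_child=dict(are), mare=mare, mre=mre, r=r)


def olp_fit(x, y, measure: str = "", fold_id: str = "") -> CalibrationModel:
    """Ordinary least products (geometric-mean) regression of y on x.

    slope = sign(r_xy) * sd(y) / sd(x); intercept = mean(y) - slope*mean(x).
    Needs >= 3 points and non-degenerate variance in both variables;
    otherwise an identity calibration is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        log.warning(
            "degenerate calibration input (n=%d); using identity calibration", x.size
        )
        return CalibrationModel(measure=measure, slope=1.0, intercept=0.0, fold_id=fold_id)
    r = np.corrcoef(x, y)[0, 1]
    sign = -1.0 if r < 0 else 1.0
    slope = sign * np.std(y) / np.std(x)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return CalibrationModel(measure=measure, slope=float(slope), intercept=intercept,
                            fold_id=fold_id)


def olp_apply(model: CalibrationModel, raw: float) -> float:
    return model.intercept + model.slope * raw


def loso_measure_eval(
    raw: dict[str, dict[str, float]],
    ref: dict[str, dict[str, float]],
    measures: list[str] | None = None,
) -> dict[str, dict]:
    """Leave-one-subject-out calibration and agreement for each measure.

    ``raw[measure][child]`` holds the automatic (uncalibrated) value and
    ``ref[measure][child]`` the reference value.  For each held-out child an
    OLP calibration is fitted on the remaining children and applied to the
    child's raw value.  Children with an undefined value are excluded from
    that measure with a log entry; children with a zero reference are
    excluded from the error summaries (the relative error is undefined).

    Returns per measure: "raw" and "adapted" AgreementMetrics and the
    per-fold calibration models.
    """
    measures = measures if measures is not None else sorted(raw)
    out: dict[str, dict] = {}
    for m in measures:
        raw_m, ref_m = raw.get(m, {}), ref.get(m, {})
        children = sorted(
            c for c in set(raw_m) & set(ref_m)
            if raw_m[c] is not None and ref_m[c] is not None
        )
        dropped = sorted((set(raw_m) | set(ref_m)) - set(children))
        if dropped:
            log.info("measure %s: excluding children with missing values: %s", m, dropped)
        adapted: dict[str, float] = {}
        calibrations: dict[str, CalibrationModel] = {}
        for held in children:
            rest = [c for c in children if c != held]
            model = olp_fit(
                [raw_m[c] for c in rest], [ref_m[c] for c in rest], measure=m, fold_id=held
            )
            calibrations[held] = model
            adapted[held] = olp_apply(model, raw_m[held])
        summaries = {}
        for kind, pred in (("raw", raw_m), ("adapted", adapted)):
            are, signed = {}, {}
            for c in children:
                e = relative_error(ref_m[c], pred[c])
                if e is not None:
                    are[c] = e
                    signed[c] = relative_error(ref_m[c], pred[c], signed=True)
            summaries[kind] = summarize(
                are, signed, {c: ref_m[c] for c in children}, {c: pred[c] for c in children}
            )
        out[m] = {"raw": summaries["raw"], "adapted": summaries["adapted"],
                  "calibrations": calibrations}
    return out
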