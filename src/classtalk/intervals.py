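"""Half-open time-interval tracks.

All timestamps in the package are integer milliseconds and every interval is
half-open, ``[onset_ms, offset_ms)``.  Overlap between two intervals (or
between an interval and a raster bin) requires a strictly positive
intersection length; touching endpoints do not overlap.

An :class:`IntervalTrack` holds the interactions of a focal child with one
partner class (``"adult"`` or ``"peer"``), either hand-coded reference
intervals or detector predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IntervalTrack",
    "merge_intervals",
    "intersection_ms",
    "rasterize_intervals",
    "intervals_from_mask",
]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort intervals and merge any that overlap or touch.

    Touching intervals ([0,5),[5,9)) are merged: a track represents *when* an
    interaction state holds, and abutting intervals describe one
    uninterrupted state.
    """
    out: list[tuple[int, int]] = []
    for onset, offset in sorted(intervals):
        if out and onset <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], offset))
        else:
            out.append((int(onset), int(offset)))
    return out


@dataclass(frozen=True)
class IntervalTrack:
    """Ordered, non-overlapping ``[onset, offset)`` intervals for one partner class."""

    partner_class: str
    intervals: tuple[tuple[int, int], ...] = ()
    source: str = "reference"  # "reference" | "predicted"

    def __post_init__(self) -> None:
        prev_off = None
        for onset, offset in self.intervals:
            if offset <= onset:
                raise ValueError(f"empty interval [{onset}, {offset})")
            if prev_off is not None and onset < prev_off:
                raise ValueError("intervals overlap or are unsorted")
            prev_off = offset

    @classmethod
    def from_intervals(
        cls, partner_class: str, intervals: list[tuple[int, int]], source: str = "reference"
    ) -> "IntervalTrack":
        """Build a valid track, merging overlapping/touching input intervals."""
        return cls(partner_class, tuple(merge_intervals(list(intervals))), source)

    def __len__(self) -> int:
        return len(self.intervals)

    def durations_ms(self) -> np.ndarray:
        return np.array([off - on for on, off in self.intervals], dtype=float)

    def total_duration_ms(self) -> int:
        return int(sum(off - on for on, off in self.intervals))

    def intersects(self, onset: int, offset: int) -> bool:
        """True if [onset, offset) has strictly positive overlap with the track."""
        return intersection_ms(self.intervals, onset, offset) > 0

    def with_source(self, source: str) -> "IntervalTrack":
        return replace(self, source=source)


def intersection_ms(intervals, onset: int, offset: int) -> int:
    """Total overlap (ms) between [onset, offset) and a sorted interval list."""
    total = 0
    for a, b in intervals:
        if a >= offset:
            break
        total += max(0, min(b, offset) - max(a, onset))
    return total


def rasterize_intervals(track: IntervalTrack, session_ms: int, dt_ms: int = 250) -> np.ndarray:
    """0/1 label per dt_ms bin; a bin is 1 iff it positively overlaps the track.

    Bin ``b`` covers ``[b*dt, (b+1)*dt)``; the raster has ``ceil(session_ms/dt)``
    bins.
    """
    if session_ms <= 0:
        raise ValueError("session_ms must be positive")
    n_bins = -(-session_ms // dt_ms)
    mask = np.zeros(n_bins, dtype=np.int8)
    for onset, offset in track.intervals:
        lo = max(0, onset // dt_ms)
        hi = min(n_bins, -(-offset // dt_ms))
        if hi > lo:
            mask[lo:hi] = 1
    return mask


def intervals_from_mask(
    mask: np.ndarray, dt_ms: int = 250, partner_class: str = "adult", source: str = "predicted"
) -> IntervalTrack:
    """Run-length encode a 0/1 per-bin trajectory into an IntervalTrack.

    Inverse of :func:`rasterize_intervals` up to bin-edge quantization.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 1:
        raise ValueError("mask must be 1-D")
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    intervals = tuple((int(s * dt_ms), int(e * dt_ms)) for s, e in zip(starts, stops))
    return IntervalTrack(partner_class, intervals, source)
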