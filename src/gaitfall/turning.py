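"""Turning-window detection and event exclusion for TUG walks.

During the mid-walk turn of a Timed-Up-and-Go test the subject briefly stops
and shuffles both feet to change direction; those adjustment contacts produce
the *lowest-valued* heel-strike maxima of the whole recording.  The window of
turning motion is located from the two deepest heel-strike peaks (pooled over
both feet):

* ``deepest_index`` / ``deepest_index2`` — frames of the globally lowest and
  second-lowest heel-strike peak values (ties broken toward earlier frames);
* ``index_before_deepest`` — the heel-strike frame immediately preceding
  ``deepest_index2`` (the last normal-pace strike before the turn);
* ``index_after_deepest`` — the heel-strike frame immediately following
  ``deepest_index`` (the first normal-pace strike after the turn);
* the window bounds are the two-point medians (floored midpoints)
  ``start = floor((index_before_deepest + deepest_index2)/2)`` and
  ``end = floor((index_after_deepest + deepest_index)/2)``.

Events falling inside the window (inclusive bounds) are excluded from gait
feature extraction, since turning motion is not normal-pace gait.  Exactly one
turning window per recording is assumed (a single TUG turn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventSeries
from .exceptions import InsufficientEventsError


@dataclass
class DeepestMaxima:
    """The two lowest-valued heel-strike peaks, tagged with their foot."""

    deepest_index: int
    deepest_index2: int
    deepest_foot: str
    deepest2_foot: str
    deepest_value: float
    deepest2_value: float


@dataclass
class TurningWindow:
    """Frame window of the turning motion, with its derivation anchors."""

    start_turning: int
    end_turning: int
    deepest_index: int
    deepest_index2: int
    index_before_deepest: int
    index_after_deepest: int
    deepest_foot: str = ""
    deepest2_foot: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_turning > self.end_turning:
            raise ValueError("start_turning must be <= end_turning")

    def contains(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames)
        return (frames >= self.start_turning) & (frames <= self.end_turning)

    def to_dict(self) -> dict:
        return {
            "start_turning": int(self.start_turning),
            "end_turning": int(self.end_turning),
            "deepest_index": int(self.deepest_index),
            "deepest_index2": int(self.deepest_index2),
            "index_before_deepest": int(self.index_before_deepest),
            "index_after_deepest": int(self.index_after_deepest),
            "deepest_foot": self.deepest_foot,
            "deepest2_foot": self.deepest2_foot,
            "flags": list(self.flags),
        }


def _pooled(left_hs: EventSeries, right_hs: EventSeries):
    frames = np.concatenate([left_hs.frame_indices, right_hs.frame_indices])
    values = np.concatenate([left_hs.peak_values, right_hs.peak_values])
    feet = np.array(["left"] * len(left_hs) + ["right"] * len(right_hs))
    order = np.argsort(frames)
    return frames[order], values[order], feet[order]


def find_deepest_maxima(left_hs: EventSeries, right_hs: EventSeries) -> DeepestMaxima:
    """Locate the two lowest-valued heel-strike peaks across both feet.

    Ties in peak value are broken toward the earlier frame.  Raises
    :class:`InsufficientEventsError` with fewer than two pooled events.
    """
    frames, values, feet = _pooled(left_hs, right_hs)
    if len(frames) < 2:
        raise InsufficientEventsError(
            f"need >= 2 heel-strike events to locate the turn, got {len(frames)}"
        )
    order = sorted(range(len(frames)), key=lambda i: (values[i], frames[i]))
    i1, i2 = order[0], order[1]
    return DeepestMaxima(
        deepest_index=int(frames[i1]),
        deepest_index2=int(frames[i2]),
        deepest_foot=str(feet[i1]),
        deepest2_foot=str(feet[i2]),
        deepest_value=float(values[i1]),
        deepest2_value=float(values[i2]),
    )


def compute_turning_window(left_hs: EventSeries, right_hs: EventSeries) -> TurningWindow:
    """Compute the turning window from both feet's heel-strike series.

    Both feet's strikes are pooled when locating the strikes immediately
    before/after the deepest pair.  If no strike exists before
    ``deepest_index2`` the start falls back to ``deepest_index2`` itself
    (flagged); symmetric fallback for the end.  Should the data yield a start
    after the end (deepest pair in reversed temporal order), the bounds are
    swapped and flagged.
    """
    dm = find_deepest_maxima(left_hs, right_hs)
    frames, _, _ = _pooled(left_hs, right_hs)
    flags: list[str] = []

    before = frames[frames < dm.deepest_index2]
    if len(before):
        index_before = int(before.max())
    else:
        index_before = dm.deepest_index2
        flags.append("no_event_before_deepest2")

    after = frames[frames > dm.deepest_index]
    if len(after):
        index_after = int(after.min())
    else:
        index_after = dm.deepest_index
        flags.append("no_event_after_deepest")

    # two-point median = midpoint, floored to a frame index
    start = (index_before + dm.deepest_index2) // 2
    end = (index_after + dm.deepest_index) // 2
    if start > end:
        start, end = end, start
        flags.append("bounds_swapped")

    return TurningWindow(
        start_turning=int(start),
        end_turning=int(end),
        deepest_index=dm.deepest_index,
        deepest_index2=dm.deepest_index2,
        index_before_deepest=index_before,
        index_after_deepest=index_after,
        deepest_foot=dm.deepest_foot,
        deepest2_foot=dm.deepest2_foot,
        flags=flags,
    )


def exclude_turning_events(events: EventSeries, window: TurningWindow) -> EventSeries:
    """Return a copy of ``events`` without frames inside the window
    (inclusive bounds).  The original series is left unmodified; applying the
    same window twice is a no-op."""
    keep = ~window.contains(events.frame_indices)
    return EventSeries(
        foot=events.foot,
        event_type=events.event_type,
        frame_indices=events.frame_indices[keep].copy(),
        peak_values=events.peak_values[keep].copy(),
        fps=events.fps,
        subject_id=events.subject_id,
    )
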