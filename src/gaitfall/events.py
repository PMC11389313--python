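"""Signal smoothing and gait-event detection.

Heel strikes and toe-offs are located as local maxima of the (image-convention,
downward-positive) vertical keypoint trajectory after Savitzky–Golay smoothing:
a foot in ground contact sits lowest in the image, i.e. at maximal y.  Heel
strikes come from the {L,R}Heel keypoints, toe-offs from {L,R}BigToe.

The Savitzky–Golay filter replaces each sample by the value at that sample of
a least-squares polynomial fitted over a centred window,

    y_hat[i] = sum_{j=-k..k} c_j * y[i+j],

which for interior samples is a fixed convolution.  Near the edges this
implementation fits the polynomial on the *truncated* window instead of
padding, so no samples are fabricated at the start or end of the walk where
events matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import peak_prominences, savgol_filter

from .exceptions import ParameterError, SignalLengthError
from .pose import PoseSequence, Signal, extract_trajectory

#: Smoothing defaults: 11-sample window, cubic polynomial.
DEFAULT_WINDOW_LENGTH = 11
DEFAULT_POLYORDER = 3

#: Minimum spacing between accepted peaks: ~0.5 s at 30 fps, below the
#: shortest plausible interval between successive same-signal contacts.
DEFAULT_MIN_DISTANCE = 15

#: Minimum peak prominence in pixels for event detection on real/noisy data.
#: The maximum of smoothed keypoint jitter over a whole recording stays below
#: ~7 px for raw pixel noise of a few px, while the smallest genuine contact
#: peak (a reduced-amplitude turning adjustment) rises >= ~20 px above swing
#: level on a 1080p foot trajectory; 10 px separates the two with margin.
DEFAULT_PROMINENCE = 10.0

_EVENT_KEYPOINT = {
    ("heel_strike", "left"): "LHeel",
    ("heel_strike", "right"): "RHeel",
    ("toe_off", "left"): "LBigToe",
    ("toe_off", "right"): "RBigToe",
}


@dataclass
class SmoothingParams:
    """Savitzky–Golay window length (odd, samples) and polynomial order."""

    window_length: int = DEFAULT_WINDOW_LENGTH
    polyorder: int = DEFAULT_POLYORDER

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ParameterError(f"window_length must be odd, got {self.window_length}")
        if self.polyorder < 0:
            raise ParameterError("polyorder must be >= 0")
        if self.polyorder >= self.window_length:
            raise ParameterError(
                f"polyorder ({self.polyorder}) must be < window_length "
                f"({self.window_length})"
            )


@dataclass
class PeakParams:
    """Peak-acceptance constraints for gait-event detection."""

    min_distance: int = DEFAULT_MIN_DISTANCE
    prominence: float | None = None

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ParameterError("min_distance must be >= 1")


@dataclass
class EventSeries:
    """Detected gait events of one type for one foot."""

    foot: str  # "left" | "right"
    event_type: str  # "heel_strike" | "toe_off"
    frame_indices: np.ndarray
    peak_values: np.ndarray
    fps: float = 30.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if self.frame_indices.shape != self.peak_values.shape:
            raise ParameterError("frame_indices and peak_values must match in length")
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise ParameterError("event frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_indices)

    @property
    def times_s(self) -> np.ndarray:
        return self.frame_indices / self.fps


def _edge_fit(values: np.ndarray, i: int, k: int, polyorder: int) -> float:
    """Least-squares polynomial value at sample i over the truncated window."""
    lo, hi = max(0, i - k), min(len(values), i + k + 1)
    x = np.arange(lo, hi) - i
    deg = min(polyorder, len(x) - 1)
    # Vandermonde least squares; evaluated at x=0 the fit equals coeffs[0]
    coeffs, *_ = np.linalg.lstsq(np.vander(x, deg + 1, increasing=True),
                                 values[lo:hi], rcond=None)
    return float(coeffs[0])


def savgol_smooth(signal: Signal, params: SmoothingParams | None = None) -> Signal:
    """Savitzky–Golay smooth a signal (same length, truncated-edge fits)."""
    params = params or SmoothingParams()
    n = len(signal)
    if n < params.window_length:
        raise SignalLengthError(
            f"signal of length {n} shorter than window {params.window_length}"
        )
    k = params.window_length // 2
    out = savgol_filter(signal.values, params.window_length, params.polyorder)
    for i in range(k):
        out[i] = _edge_fit(signal.values, i, k, params.polyorder)
        out[n - 1 - i] = _edge_fit(signal.values, n - 1 - i, k, params.polyorder)
    return Signal(out, signal.frame_indices.copy(), fps=signal.fps,
                  interpolated=signal.interpolated)


def _plateau_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; a flat plateau counts once, at its
    first index (deterministic tie rule)."""
    n = len(values)
    cands: list[int] = []
    i = 1
    while i < n - 1:
        if values[i] <= values[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if j + 1 < n and values[j + 1] < values[i]:
            cands.append(i)
        i = j + 1
    return cands


def find_local_maxima(signal: Signal, params: PeakParams | None = None) -> np.ndarray:
    """Constrained local maxima of a signal, as sample positions.

    Candidates are samples strictly greater than both neighbours (plateaus
    count once, at their first sample).  An optional prominence threshold
    discards shallow maxima, then candidates are greedily filtered highest
    value first so that surviving peaks are at least ``min_distance`` samples
    apart; on a conflict the higher peak wins (ties: earlier sample).

    Returns positions into ``signal.values`` (identical to frame indices for
    gap-free sequences).  Empty array when no peaks qualify.
    """
    params = params or PeakParams()
    values = signal.values
    if len(values) < 3:
        return np.array([], dtype=int)
    cands = _plateau_maxima(values)
    if params.prominence is not None and cands:
        prom = peak_prominences(values, np.asarray(cands, dtype=int))[0]
        cands = [c for c, p in zip(cands, prom) if p >= params.prominence]
    accepted: list[int] = []
    for c in sorted(cands, key=lambda c: (-values[c], c)):
        if all(abs(c - a) >= params.min_distance for a in accepted):
            accepted.append(c)
    return np.array(sorted(accepted), dtype=int)


def detect_events(
    seq: PoseSequence,
    foot: str,
    event_type: str,
    smoothing: SmoothingParams | None = None,
    peaks: PeakParams | None = None,
    y_up: bool = False,
) -> EventSeries:
    """Detect heel-strike or toe-off events for one foot of a sequence.

    Pipeline: extract the relevant keypoint's y trajectory, Savitzky–Golay
    smooth it, and accept constrained local maxima as events.  With
    ``y_up=True`` the signal is negated first (for datasets whose y axis
    points up, where ground contact is a minimum).
    """
    try:
        keypoint = _EVENT_KEYPOINT[(event_type, foot)]
    except KeyError:
        raise ParameterError(
            f"unknown event/foot combination ({event_type!r}, {foot!r})"
        ) from None
    if peaks is None:
        peaks = PeakParams(prominence=DEFAULT_PROMINENCE)
    sig = extract_trajectory(seq, keypoint, "y")
    if y_up:
        sig = Signal(-sig.values, sig.frame_indices, fps=sig.fps,
                     interpolated=sig.interpolated)
    smoothed = savgol_smooth(sig, smoothing)
    pos = find_local_maxima(smoothed, peaks)
    return EventSeries(
        foot=foot,
        event_type=event_type,
        frame_indices=smoothed.frame_indices[pos],
        peak_values=smoothed.values[pos],
        fps=seq.fps,
        subject_id=seq.subject_id,
    )


def detect_all_events(
    seq: PoseSequence,
    smoothing: SmoothingParams | None = None,
    peaks: PeakParams | None = None,
    y_up: bool = False,
) -> dict[tuple[str, str], EventSeries]:
    """Detect all four event series, keyed by (foot, event_type)."""
    return {
        (foot, etype): detect_events(seq, foot, etype, smoothing, peaks, y_up)
        for foot in ("left", "right")
        for etype in ("heel_strike", "toe_off")
    }
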