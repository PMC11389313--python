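"""Pose-estimation keypoint I/O.

Reads the per-frame keypoint output of a Halpe full-body (26 keypoint) pose
estimator — the AlphaPose results-JSON dialect or a simple wide CSV — into a
:class:`PoseSequence`, and exposes named keypoint coordinates as time-series
:class:`Signal` objects ready for smoothing and gait-event detection.

Coordinates follow the image convention: *y increases downward*, so a foot in
ground contact sits at a local *maximum* of its raw y trajectory.  Datasets
with upward-positive y can be handled by passing ``y_up=True`` downstream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    EmptySignalError,
    GaitError,
    SchemaError,
)

#: The 26 Halpe full-body keypoint names, in the estimator's fixed output order.
HALPE26_KEYPOINTS: tuple[str, ...] = (
    "Nose", "LEye", "REye", "LEar", "REar",
    "LShoulder", "RShoulder", "LElbow", "RElbow", "LWrist", "RWrist",
    "LHip", "RHip", "LKnee", "RKnee", "LAnkle", "RAnkle",
    "Head", "Neck", "Hip",
    "LBigToe", "RBigToe", "LSmallToe", "RSmallToe", "LHeel", "RHeel",
)

_KEYPOINT_INDEX = {name: i for i, name in enumerate(HALPE26_KEYPOINTS)}

#: Keypoints required for temporal gait analysis.
GAIT_KEYPOINTS: tuple[str, ...] = ("LHeel", "RHeel", "LBigToe", "RBigToe")

#: Default frame rate when metadata is absent (side/front TUG recordings).
DEFAULT_FPS: float = 30.0

#: Samples with confidence below this are treated as missing.
DEFAULT_CONFIDENCE_THRESHOLD: float = 0.1

N_KEYPOINTS = len(HALPE26_KEYPOINTS)
_FLAT_LEN = 3 * N_KEYPOINTS


@dataclass
class Signal:
    """A real-valued sample series over video frames.

    Attributes
    ----------
    values : ndarray of float
        Sample values (pixels or arbitrary units).
    frame_indices : ndarray of int
        Strictly increasing sample positions (0-based frames).
    fps : float
        Frames per second.
    interpolated : ndarray of bool, optional
        Mask flagging samples that were filled in (missing in the source).
    """

    values: np.ndarray
    frame_indices: np.ndarray
    fps: float = DEFAULT_FPS
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.values.shape != self.frame_indices.shape:
            raise SchemaError("values and frame_indices must have equal length")
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise SchemaError("frame_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return self.frame_indices / self.fps


@dataclass
class PoseSequence:
    """Ordered per-frame keypoint records for one recording.

    ``keypoints`` has shape ``(n_frames, 26, 3)`` with columns x, y,
    confidence in the Halpe order.  Frame indexing is 0-based.
    """

    keypoints: np.ndarray
    frame_indices: np.ndarray
    fps: float = DEFAULT_FPS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (N_KEYPOINTS, 3):
            raise SchemaError(
                f"keypoints must have shape (n, {N_KEYPOINTS}, 3), "
                f"got {self.keypoints.shape}"
            )
        if len(self.frame_indices) != len(self.keypoints):
            raise SchemaError("frame_indices length must match keypoints")

    def __len__(self) -> int:
        return len(self.keypoints)

    def keypoint_array(self, name: str) -> np.ndarray:
        """Return the (n_frames, 3) x/y/confidence array for one keypoint."""
        try:
            idx = _KEYPOINT_INDEX[name]
        except KeyError:
            raise KeyError(
                f"unknown keypoint {name!r}; expected one of {HALPE26_KEYPOINTS}"
            ) from None
        return self.keypoints[:, idx, :]


@dataclass
class Issue:
    level: str  # "warning" | "fatal"
    code: str
    message: str
    start: int | None = None
    end: int | None = None


@dataclass
class SequenceReport:
    """Report from :func:`validate_sequence` (report-only, never raises)."""

    n_frames: int
    duration_s: float
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.level == "fatal" for i in self.issues)


def _frame_number(image_id) -> int:
    """Parse a frame number out of an AlphaPose image identifier."""
    if isinstance(image_id, (int, np.integer)):
        return int(image_id)
    m = re.search(r"(\d+)", str(image_id))
    if m is None:
        raise SchemaError(f"cannot parse frame number from image_id {image_id!r}")
    return int(m.group(1))


def read_pose_json(path, fps: float = DEFAULT_FPS, subject_id: str = "") -> PoseSequence:
    """Read an AlphaPose-style results JSON into a :class:`PoseSequence`.

    The file is a list of per-detection records, each with an image identifier
    and a flat ``keypoints`` array of 26 (x, y, confidence) triplets.  Multiple
    detections on the same frame are collapsed to the one with the highest
    summed confidence (single-subject recording assumption).
    """
    text = Path(path).read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: file is empty")
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GaitError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(records, list):
        raise SchemaError(f"{path}: expected a top-level list of detections")
    if not records:
        raise EmptyInputError(f"{path}: no detections")

    best: dict[int, tuple[float, np.ndarray]] = {}
    for rec in records:
        kps = np.asarray(rec["keypoints"], dtype=float)
        if kps.size % 3 != 0 or kps.size != _FLAT_LEN:
            raise SchemaError(
                f"{path}: keypoints array of length {kps.size}; expected {_FLAT_LEN}"
            )
        frame = _frame_number(rec.get("image_id", rec.get("frame", 0)))
        kps = kps.reshape(N_KEYPOINTS, 3)
        total_conf = float(kps[:, 2].sum())
        if frame not in best or total_conf > best[frame][0]:
            best[frame] = (total_conf, kps)

    frames = np.array(sorted(best), dtype=int)
    keypoints = np.stack([best[f][1] for f in frames])
    return PoseSequence(keypoints, frames, fps=fps, subject_id=subject_id)


def write_pose_json(seq: PoseSequence, path) -> None:
    """Write a sequence back to the AlphaPose results-JSON dialect.

    Round-trips bit-exactly with :func:`read_pose_json` (JSON floats preserve
    the full double precision).
    """
    records = []
    for frame, kps in zip(seq.frame_indices, seq.keypoints):
        records.append(
            {
                "image_id": f"{int(frame)}.jpg",
                "keypoints": [float(v) for v in kps.reshape(-1)],
                "score": float(kps[:, 2].mean()),
            }
        )
    Path(path).write_text(json.dumps(records))


def read_pose_csv(path, fps: float = DEFAULT_FPS, subject_id: str = "") -> PoseSequence:
    """Read a wide CSV (frame, <Name>_x, <Name>_y, <Name>_c) sequence."""
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no rows")
    if "frame" not in df.columns:
        raise SchemaError(f"{path}: missing 'frame' column")
    n = len(df)
    keypoints = np.zeros((n, N_KEYPOINTS, 3))
    for i, name in enumerate(HALPE26_KEYPOINTS):
        for j, suffix in enumerate(("x", "y", "c")):
            col = f"{name}_{suffix}"
            if col not in df.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
            keypoints[:, i, j] = df[col].to_numpy(dtype=float)
    return PoseSequence(keypoints, df["frame"].to_numpy(dtype=int), fps=fps,
                        subject_id=subject_id)


def extract_trajectory(
    seq: PoseSequence,
    keypoint_name: str,
    axis: str = "y",
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> Signal:
    """Extract one coordinate of one keypoint over all frames as a Signal.

    Samples whose confidence falls below ``confidence_threshold`` (or that are
    NaN) are treated as missing: interior gaps are linearly interpolated
    between the nearest valid neighbours, leading/trailing gaps are held at
    the nearest valid value.  Filled samples are flagged in
    ``Signal.interpolated``; interpolation never extrapolates.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    arr = seq.keypoint_array(keypoint_name)
    values = arr[:, 0 if axis == "x" else 1].copy()
    conf = arr[:, 2]
    missing = (conf < confidence_threshold) | ~np.isfinite(values)
    if missing.all():
        raise EmptySignalError(
            f"all {len(values)} samples of {keypoint_name}.{axis} are missing"
        )
    if missing.any():
        valid_idx = np.flatnonzero(~missing)
        # np.interp holds edge values constant outside [first, last] valid sample
        values[missing] = np.interp(
            seq.frame_indices[missing],
            seq.frame_indices[valid_idx],
            values[valid_idx],
        )
    return Signal(values, seq.frame_indices.copy(), fps=seq.fps,
                  interpolated=missing)


def validate_sequence(
    seq: PoseSequence,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> SequenceReport:
    """Sanity-check a sequence; returns a report, never raises.

    Reported issues: non-positive fps (fatal), fps differing from the 30 fps
    recording convention (warning), gaps in the frame index (warning with
    start/end), frames missing any of the four gait keypoints (warning).
    """
    duration = len(seq) / seq.fps if seq.fps > 0 else float("nan")
    report = SequenceReport(n_frames=len(seq), duration_s=duration)
    if seq.fps <= 0:
        report.issues.append(Issue("fatal", "bad_fps", f"fps must be > 0, got {seq.fps}"))
    elif seq.fps != DEFAULT_FPS:
        report.issues.append(
            Issue("warning", "nonstandard_fps",
                  f"fps is {seq.fps}, recordings are normally {DEFAULT_FPS}")
        )
    if len(seq) == 0:
        report.issues.append(Issue("fatal", "empty", "sequence has no frames"))
        return report

    diffs = np.diff(seq.frame_indices)
    for pos in np.flatnonzero(diffs > 1):
        report.issues.append(
            Issue("warning", "frame_gap",
                  f"gap of {diffs[pos] - 1} frames",
                  start=int(seq.frame_indices[pos]),
                  end=int(seq.frame_indices[pos + 1]))
        )

    missing_gait = 0
    for name in GAIT_KEYPOINTS:
        conf = seq.keypoint_array(name)[:, 2]
        missing_gait += int(np.count_nonzero(conf < confidence_threshold))
    if missing_gait:
        report.issues.append(
            Issue("warning", "missing_gait_keypoints",
                  f"{missing_gait} gait-keypoint samples below confidence "
                  f"{confidence_threshold} (will be interpolated)")
        )
    return report


def signals_frame(seq: PoseSequence, keypoints=GAIT_KEYPOINTS, axis: str = "y") -> pd.DataFrame:
    """Tabulate selected keypoint trajectories as a wide DataFrame."""
    data = {"frame": seq.frame_indices}
    for name in keypoints:
        data[f"{name}_{axis}"] = extract_trajectory(seq, name, axis).values
    return pd.DataFrame(data)
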