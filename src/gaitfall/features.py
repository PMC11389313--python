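"""Temporal gait features from turning-excluded event series.

The four temporal features, all derived from heel-strike (HS) and toe-off
(TO) frame indices at a known frame rate:

* stance time  = (TO − HS) / fps         — same foot, within one gait cycle;
* stride time  = (HS_{i+1} − HS_i) / fps — successive strikes of the same foot;
* step time    = (oppTO_i − HS_i) / fps  — heel strike to the *opposite*
  foot's following toe-off (the source convention; the conventional
  heel-strike-to-opposite-heel-strike definition is available via
  ``step_time_convention="contralateral_hs"``);
* cadence      = steps per minute, counted as completed step intervals over
  the straight-walk segments (the turning pause contributes neither steps nor
  duration).

One aggregate row per subject is produced (mean over all valid cycles), in
either the per-foot schema (Experiment 1) or the averaged schema
(Experiment 2).  Event pairs spanning the excluded turning window are never
formed: each foot's events are segmented at the window and cycles are built
within segments only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventSeries
from .exceptions import (
    EventOrderingError,
    FeatureExtractionError,
    MappingError,
    ParameterError,
    PairingError,
    SchemaError,
)
from .turning import TurningWindow

#: Exact Experiment-1 (per-foot) CSV header.
PER_FOOT_COLUMNS = [
    "left_stride_time", "right_stride_time",
    "left_step_time", "right_step_time",
    "left_stance_time", "right_stance_time",
    "cadence", "label",
]

#: Exact Experiment-2 (averaged) CSV header.
AVERAGED_COLUMNS = [
    "average_stride_time", "average_step_time", "average_stance_time",
    "cadence", "label",
]

PER_FOOT_FEATURES = PER_FOOT_COLUMNS[:-1]
AVERAGED_FEATURES = AVERAGED_COLUMNS[:-1]

LABELS = ("non_faller", "faller")

#: External (elderly POMA cohort) column -> per-foot schema column.
EXTERNAL_ATTRIBUTE_MAP = {
    "Left_Stride_Time": "left_stride_time",
    "Right_Stride_Time": "right_stride_time",
    "Left_Step_Time": "left_step_time",
    "Right_Step_Time": "right_step_time",
    "Left_Single_Support": "left_stance_time",
    "Right_Single_Support": "right_stance_time",
}


def stance_time(heel_strike: int, toe_off: int, fps: float) -> float:
    """Seconds one foot spends on the ground: (toe_off − heel_strike)/fps."""
    if fps <= 0:
        raise ParameterError(f"fps must be > 0, got {fps}")
    if toe_off <= heel_strike:
        raise EventOrderingError(
            f"toe-off frame {toe_off} must follow heel-strike frame {heel_strike}"
        )
    return (toe_off - heel_strike) / fps


def stride_time(hs_i: int, hs_next: int, fps: float) -> float:
    """Seconds between successive heel strikes of the same foot."""
    if fps <= 0:
        raise ParameterError(f"fps must be > 0, got {fps}")
    if hs_next <= hs_i:
        raise EventOrderingError(
            f"next heel strike {hs_next} must follow heel strike {hs_i}"
        )
    return (hs_next - hs_i) / fps


def step_time(hs_i: int, opposite_toe_off_i: int, fps: float) -> float:
    """Seconds from a heel strike to the opposite foot's following toe-off."""
    if fps <= 0:
        raise ParameterError(f"fps must be > 0, got {fps}")
    if opposite_toe_off_i <= hs_i:
        raise PairingError(
            f"opposite toe-off {opposite_toe_off_i} must follow heel strike {hs_i}"
        )
    return (opposite_toe_off_i - hs_i) / fps


def cadence(n_steps: int, duration_min: float) -> float:
    """Steps per minute: n_steps / duration_min."""
    if duration_min <= 0:
        raise ParameterError(f"duration must be > 0 minutes, got {duration_min}")
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    return n_steps / duration_min


@dataclass
class GaitFeatureRow:
    """One subject's aggregated temporal gait features (per-foot layout)."""

    subject_id: str
    left_stride_time: float
    right_stride_time: float
    left_step_time: float
    right_step_time: float
    left_stance_time: float
    right_stance_time: float
    cadence: float
    label: str | None = None

    def to_dict(self, schema: str = "per_foot") -> dict:
        if schema == "per_foot":
            return {
                "left_stride_time": self.left_stride_time,
                "right_stride_time": self.right_stride_time,
                "left_step_time": self.left_step_time,
                "right_step_time": self.right_step_time,
                "left_stance_time": self.left_stance_time,
                "right_stance_time": self.right_stance_time,
                "cadence": self.cadence,
                "label": self.label,
            }
        if schema == "averaged":
            return {
                "average_stride_time": (self.left_stride_time + self.right_stride_time) / 2,
                "average_step_time": (self.left_step_time + self.right_step_time) / 2,
                "average_stance_time": (self.left_stance_time + self.right_stance_time) / 2,
                "cadence": self.cadence,
                "label": self.label,
            }
        raise SchemaError(f"unknown schema {schema!r}")


def _segments(frames: np.ndarray, window: TurningWindow | None) -> list[np.ndarray]:
    """Split event frames into straight-walk segments at the turning window."""
    frames = np.asarray(frames, dtype=int)
    if window is None:
        return [frames] if len(frames) else []
    segs = [frames[frames < window.start_turning],
            frames[frames > window.end_turning]]
    return [s for s in segs if len(s)]


def _in_same_segment(frame: int, window: TurningWindow | None):
    if window is None:
        return lambda f: True
    if frame < window.start_turning:
        return lambda f: f < window.start_turning
    return lambda f: f > window.end_turning


def _mean_or_fail(values: list[float], what: str, foot: str) -> float:
    if not values:
        raise FeatureExtractionError(f"no valid {what} cycles for the {foot} foot")
    return float(np.mean(values))


def build_feature_row(
    left_events: tuple[EventSeries, EventSeries],
    right_events: tuple[EventSeries, EventSeries],
    window: TurningWindow | None,
    fps: float,
    schema: str = "per_foot",
    step_time_convention: str = "paper",
    subject_id: str = "",
    label: str | None = None,
) -> GaitFeatureRow:
    """Aggregate one subject's temporal gait features from event series.

    Parameters
    ----------
    left_events, right_events : (heel_strike EventSeries, toe_off EventSeries)
        Detected events per foot, *before* turning exclusion (the window is
        applied here so that no cycle spans the turn).
    window : TurningWindow or None
        Turning window to exclude; None for recordings without a turn.
    step_time_convention : {"paper", "contralateral_hs"}
        "paper" pairs each heel strike with the opposite foot's next toe-off;
        "contralateral_hs" with the opposite foot's next heel strike.
    """
    if schema not in ("per_foot", "averaged"):
        raise SchemaError(f"unknown schema {schema!r}")
    if step_time_convention not in ("paper", "contralateral_hs"):
        raise ParameterError(f"unknown step_time_convention {step_time_convention!r}")
    if fps <= 0:
        raise ParameterError(f"fps must be > 0, got {fps}")

    series = {"left": left_events, "right": right_events}
    surviving: dict[str, dict[str, np.ndarray]] = {}
    for foot, (hs, to) in series.items():
        keep_hs = hs.frame_indices[~window.contains(hs.frame_indices)] if window is not None else hs.frame_indices
        keep_to = to.frame_indices[~window.contains(to.frame_indices)] if window is not None else to.frame_indices
        if len(keep_hs) < 2:
            raise FeatureExtractionError(
                f"{foot} foot has {len(keep_hs)} heel strikes after turning "
                "exclusion; need >= 2"
            )
        if len(keep_to) < 1:
            raise FeatureExtractionError(
                f"{foot} foot has no toe-offs after turning exclusion"
            )
        surviving[foot] = {"hs": np.asarray(keep_hs), "to": np.asarray(keep_to)}

    out: dict[str, float] = {}
    for foot in ("left", "right"):
        opp = "right" if foot == "left" else "left"
        hs_frames = surviving[foot]["hs"]
        to_frames = surviving[foot]["to"]
        opp_target = (surviving[opp]["to"] if step_time_convention == "paper"
                      else surviving[opp]["hs"])

        strides: list[float] = []
        for seg in _segments(hs_frames, window):
            strides.extend(stride_time(a, b, fps) for a, b in zip(seg[:-1], seg[1:]))
        out[f"{foot}_stride_time"] = _mean_or_fail(strides, "stride", foot)

        stances: list[float] = []
        for i, h in enumerate(hs_frames):
            same_seg = _in_same_segment(int(h), window)
            nxt = hs_frames[i + 1] if i + 1 < len(hs_frames) else np.inf
            cand = to_frames[(to_frames > h) & (to_frames < nxt)]
            cand = [c for c in cand if same_seg(c)]
            if cand:
                stances.append(stance_time(int(h), int(min(cand)), fps))
        out[f"{foot}_stance_time"] = _mean_or_fail(stances, "stance", foot)

        steps: list[float] = []
        for i, h in enumerate(hs_frames):
            # the opposite event must fall within this gait cycle: after the
            # strike but before the same foot strikes again
            same_seg = _in_same_segment(int(h), window)
            nxt = hs_frames[i + 1] if i + 1 < len(hs_frames) else np.inf
            cand = [c for c in opp_target[(opp_target > h) & (opp_target < nxt)]
                    if same_seg(c)]
            if cand:
                steps.append(step_time(int(h), int(min(cand)), fps))
        out[f"{foot}_step_time"] = _mean_or_fail(steps, "step", foot)

    # cadence: completed step intervals per straight-walk segment
    pooled_hs = np.sort(np.concatenate([surviving["left"]["hs"],
                                        surviving["right"]["hs"]]))
    n_steps = 0
    duration_frames = 0
    for seg in _segments(pooled_hs, window):
        if len(seg) >= 2:
            n_steps += len(seg) - 1
            duration_frames += int(seg[-1] - seg[0])
    if duration_frames == 0:
        raise FeatureExtractionError("zero walking duration; cannot compute cadence")
    out["cadence"] = cadence(n_steps, duration_frames / fps / 60.0)

    return GaitFeatureRow(
        subject_id=subject_id,
        left_stride_time=out["left_stride_time"],
        right_stride_time=out["right_stride_time"],
        left_step_time=out["left_step_time"],
        right_step_time=out["right_step_time"],
        left_stance_time=out["left_stance_time"],
        right_stance_time=out["right_stance_time"],
        cadence=out["cadence"],
        label=label,
    )


def detect_schema(table: pd.DataFrame) -> str:
    """Identify which experiment layout a feature table uses."""
    cols = set(table.columns)
    if set(PER_FOOT_COLUMNS) <= cols:
        return "per_foot"
    if set(AVERAGED_COLUMNS) <= cols:
        return "averaged"
    raise SchemaError(
        f"table columns {sorted(cols)} match neither the per-foot nor the "
        "averaged feature schema"
    )


def to_averaged_schema(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministically derive the averaged (Experiment-2) table from the
    per-foot (Experiment-1) table by pairwise left/right means."""
    if detect_schema(table) == "averaged":
        return table.copy()
    out = pd.DataFrame(index=table.index)
    for feat in ("stride_time", "step_time", "stance_time"):
        out[f"average_{feat}"] = (table[f"left_{feat}"] + table[f"right_{feat}"]) / 2
    out["cadence"] = table["cadence"]
    out["label"] = table["label"]
    for extra in ("subject_id", "provenance"):
        if extra in table.columns:
            out[extra] = table[extra]
    return out


def _normalise_label(value) -> str:
    s = str(value).strip().lower().replace("-", "_").replace(" ", "_")
    if s in ("faller", "1", "true", "high_risk"):
        return "faller"
    if s in ("non_faller", "nonfaller", "0", "false", "low_risk"):
        return "non_faller"
    raise MappingError(f"unrecognised label value {value!r}")


def map_external_attributes(external: pd.DataFrame) -> pd.DataFrame:
    """Map an external-dialect gait table onto the per-foot schema.

    Renames ``Left/Right_Stride_Time`` and ``Left/Right_Step_Time``, maps the
    single-support columns to stance times, averages ``Left_Cadence`` and
    ``Right_Cadence`` into ``cadence``, normalises the label, and drops any
    extra (spatial) columns.  Raises :class:`MappingError` listing every
    missing mandatory column.
    """
    single = False
    if isinstance(external, (pd.Series, dict)):
        external = pd.DataFrame([dict(external)])
        single = True
    required = list(EXTERNAL_ATTRIBUTE_MAP) + ["Left_Cadence", "Right_Cadence"]
    missing = [c for c in required if c not in external.columns]
    if "label" not in external.columns and "Label" not in external.columns:
        missing.append("label")
    if missing:
        raise MappingError(f"external table missing mandatory columns: {missing}")

    out = pd.DataFrame(index=external.index)
    for src, dst in EXTERNAL_ATTRIBUTE_MAP.items():
        out[dst] = external[src].astype(float)
    out["cadence"] = (external["Left_Cadence"].astype(float)
                      + external["Right_Cadence"].astype(float)) / 2
    label_col = "label" if "label" in external.columns else "Label"
    out["label"] = external[label_col].map(_normalise_label)
    out = out[PER_FOOT_COLUMNS]
    return out.iloc[0] if single else out


def merge_tables(primary: pd.DataFrame, external: pd.DataFrame) -> pd.DataFrame:
    """Concatenate two feature tables of the same schema.

    Adds/preserves a ``provenance`` column ("primary" / "external" defaults)
    and normalises labels.  Raises :class:`SchemaError` on schema mismatch.
    """
    if len(external) == 0:
        merged = primary.copy()
        if "provenance" not in merged.columns:
            merged["provenance"] = "primary"
        merged["label"] = merged["label"].map(_normalise_label)
        return merged.reset_index(drop=True)
    if detect_schema(primary) != detect_schema(external):
        raise SchemaError("cannot merge tables with different schemas")
    parts = []
    for df, default in ((primary, "primary"), (external, "external")):
        part = df.copy()
        if "provenance" not in part.columns:
            part["provenance"] = default
        part["label"] = part["label"].map(_normalise_label)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_feature_csv(table: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a feature table with the exact experiment CSV header
    (bookkeeping columns such as subject_id/provenance are not emitted)."""
    schema = schema or detect_schema(table)
    cols = PER_FOOT_COLUMNS if schema == "per_foot" else AVERAGED_COLUMNS
    table[cols].to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    """Read a feature CSV (either schema); validates the header."""
    table = pd.read_csv(path)
    detect_schema(table)
    return table
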