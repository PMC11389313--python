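"""Synthetic Timed-Up-and-Go data with known ground truth.

Two generators make every pipeline stage testable without video data:

* :func:`simulate_tug` builds per-frame 26-keypoint pose sequences for an
  out-and-back walk at 30 fps with a mid-sequence turning pause.  Each ground
  contact of a foot appears in that foot's vertical (image-convention,
  downward-positive) heel/toe trajectory as a raised-cosine bump peaked
  exactly at the event frame, riding on the swing-level baseline — so contact
  equals a local maximum of y, the smoothed maximum stays at the true frame,
  and the true event frames, turning window and feature values are known by
  construction.  The two turning adjustment contacts are generated with
  reduced bump amplitude, making their heel-strike peaks the lowest-valued
  maxima of the recording (the premise the turning detector relies on).

* :func:`simulate_feature_table` draws per-subject feature rows from
  truncated-normal class distributions encoding the faller/non-faller
  contrasts the analysis assumes: fallers with longer stance and stride
  times, higher cadence, shorter step times and wider stride-time spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .events import EventSeries
from .exceptions import ParameterError
from .features import GaitFeatureRow, build_feature_row
from .pose import (
    GAIT_KEYPOINTS,
    HALPE26_KEYPOINTS,
    N_KEYPOINTS,
    PoseSequence,
)
from .turning import TurningWindow


@dataclass
class GaitSimParams:
    """Kinematic parameters of one simulated TUG walk.

    Durations in seconds, amplitudes in pixels.  Defaults emulate the study
    protocol: a 3 m out-and-back walk at normal pace recorded at 30 fps —
    three strides per foot each way at a 1.2 s stride period, a 2 s turning
    pause, and a ~40 px vertical foot excursion at 1080p.
    """

    fps: float = 30.0
    n_strides_out: int = 3
    n_strides_back: int = 3
    stride_period: float = 1.2
    stance_fraction: float = 0.6
    step_phase_offset: float = 0.5
    foot_lift_amplitude: float = 40.0
    baseline_y: float = 600.0
    turn_pause: float = 2.0
    turn_depth_factor: float = 0.6
    noise_sigma: float = 0.0
    lead_in: float = 1.0
    seed: int = 0
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.stride_period <= 0:
            raise ParameterError("stride_period must be > 0")
        if not 0 < self.stance_fraction < 1:
            raise ParameterError(
                f"stance_fraction must lie in (0,1): stance duration "
                f"{self.stance_fraction * self.stride_period:.3f}s must be "
                f"shorter than the stride period {self.stride_period:.3f}s"
            )
        if self.turn_pause < 0:
            raise ParameterError("turn_pause must be >= 0")
        if self.n_strides_out < 2 or self.n_strides_back < 2:
            raise ParameterError("need >= 2 strides per foot in each direction")
        if not 0 < self.turn_depth_factor <= 0.8:
            raise ParameterError("turn_depth_factor must lie in (0, 0.8]")
        if self.turn_pause > 0:
            needed = self.stance_fraction * self.stride_period / 0.4
            if self.turn_pause < needed:
                raise ParameterError(
                    f"turn_pause {self.turn_pause}s too short to hold the two "
                    f"adjustment contacts; need >= {needed:.2f}s"
                )


@dataclass
class FootTruth:
    """True event frames of one foot (straight-walk and turning contacts)."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    turn_heel_strikes: np.ndarray
    turn_toe_offs: np.ndarray

    def all_heel_strikes(self) -> np.ndarray:
        return np.sort(np.concatenate([self.heel_strikes, self.turn_heel_strikes]))

    def all_toe_offs(self) -> np.ndarray:
        return np.sort(np.concatenate([self.toe_offs, self.turn_toe_offs]))


@dataclass
class GroundTruth:
    """Simulator-side truth: events, turning window, and parameters."""

    left: FootTruth
    right: FootTruth
    turn_start_frame: int
    turn_end_frame: int
    params: GaitSimParams

    def turning_window(self) -> TurningWindow:
        """The true turning window as an exclusion window."""
        return TurningWindow(
            start_turning=self.turn_start_frame,
            end_turning=self.turn_end_frame,
            deepest_index=self.turn_start_frame,
            deepest_index2=self.turn_end_frame,
            index_before_deepest=self.turn_start_frame,
            index_after_deepest=self.turn_end_frame,
            flags=["ground_truth"],
        )

    def event_series(self, foot: str, event_type: str) -> EventSeries:
        ft = self.left if foot == "left" else self.right
        frames = (ft.all_heel_strikes() if event_type == "heel_strike"
                  else ft.all_toe_offs())
        return EventSeries(
            foot=foot,
            event_type=event_type,
            frame_indices=frames,
            peak_values=np.full(len(frames), self.params.baseline_y),
            fps=self.params.fps,
            subject_id=self.params.subject_id,
        )


def _frame(t: float, fps: float) -> int:
    return int(np.floor(t * fps + 0.5))


def _schedule(params: GaitSimParams):
    """Event times (s) per foot: [(hs, to, is_turn), ...], plus turn bounds."""
    T = params.stride_period
    off = params.step_phase_offset * T
    stance = params.stance_fraction * T
    t0 = params.lead_in

    contacts = {"left": [], "right": []}
    for i in range(params.n_strides_out):
        contacts["left"].append((t0 + i * T, False))
        contacts["right"].append((t0 + off + i * T, False))
    last_out = t0 + off + (params.n_strides_out - 1) * T

    turn_start = last_out + off
    turn_end = turn_start + params.turn_pause
    if params.turn_pause > 0:
        contacts["left"].append((turn_start + 0.25 * params.turn_pause, True))
        contacts["right"].append((turn_start + 0.60 * params.turn_pause, True))

    for i in range(params.n_strides_back):
        contacts["left"].append((turn_end + i * T, False))
        contacts["right"].append((turn_end + off + i * T, False))

    events = {
        foot: [(t, t + stance, is_turn) for t, is_turn in sorted(cs)]
        for foot, cs in contacts.items()
    }
    return events, turn_start, turn_end


def _bump_signal(n_frames: int, centers_frames, amplitudes, width_frames: float,
                 swing_level: float) -> np.ndarray:
    """Raised-cosine bumps of the given width on a flat swing baseline."""
    y = np.full(n_frames, swing_level)
    f = np.arange(n_frames)
    half = width_frames / 2.0
    for c, a in zip(centers_frames, amplitudes):
        mask = np.abs(f - c) <= half
        y[mask] += a * 0.5 * (1.0 + np.cos(np.pi * (f[mask] - c) / half))
    return y


def simulate_tug(params: GaitSimParams | None = None) -> tuple[PoseSequence, GroundTruth]:
    """Generate a synthetic TUG pose sequence with ground truth.

    Deterministic for identical parameters and seed.  With
    ``noise_sigma = 0`` the event-detection pipeline recovers every true
    event frame exactly.
    """
    params = params or GaitSimParams()
    rng = np.random.default_rng(params.seed)
    fps = params.fps
    T = params.stride_period
    stance = params.stance_fraction * T
    width_frames = stance * fps

    events, turn_start, turn_end = _schedule(params)
    last_event = max(to for foot in events.values() for _, to, _ in foot)
    n_frames = _frame(last_event + params.lead_in, fps) + 1

    truth_feet: dict[str, FootTruth] = {}
    signals: dict[str, np.ndarray] = {}
    for foot, evts in events.items():
        hs = np.array([_frame(t, fps) for t, _, turn in evts if not turn])
        to = np.array([_frame(t, fps) for _, t, turn in evts if not turn])
        ths = np.array([_frame(t, fps) for t, _, turn in evts if turn], dtype=int)
        tto = np.array([_frame(t, fps) for _, t, turn in evts if turn], dtype=int)
        truth_feet[foot] = FootTruth(hs, to, ths, tto)

        lift = params.foot_lift_amplitude
        swing_level = params.baseline_y - lift
        # Both adjustment contacts sit below every normal-pace peak, and the
        # temporally *second* one (the right foot's, per the schedule) is the
        # deepest: the strike right after the deepest peak is then the first
        # post-turn heel strike, which is what the turning detector assumes.
        factor = (params.turn_depth_factor if foot == "right"
                  else min(params.turn_depth_factor + 0.15, 0.95))
        hs_centers = np.concatenate([hs, ths])
        hs_amps = np.concatenate([np.full(len(hs), lift),
                                  np.full(len(ths), lift * factor)])
        to_centers = np.concatenate([to, tto])
        to_amps = hs_amps
        heel = _bump_signal(n_frames, hs_centers, hs_amps, width_frames, swing_level)
        toe = _bump_signal(n_frames, to_centers, to_amps, width_frames, swing_level)
        side = "L" if foot == "left" else "R"
        signals[f"{side}Heel"] = heel
        signals[f"{side}BigToe"] = toe

    keypoints = np.zeros((n_frames, N_KEYPOINTS, 3))
    keypoints[:, :, 2] = 0.9
    # non-gait keypoints: plausible static body positions above the feet
    for i, name in enumerate(HALPE26_KEYPOINTS):
        keypoints[:, i, 0] = 400.0
        keypoints[:, i, 1] = 300.0
    for name, y in signals.items():
        i = HALPE26_KEYPOINTS.index(name)
        if params.noise_sigma > 0:
            y = y + rng.normal(0.0, params.noise_sigma, n_frames)
        keypoints[:, i, 0] = 400.0
        keypoints[:, i, 1] = y
        keypoints[:, i, 2] = 1.0

    seq = PoseSequence(keypoints, np.arange(n_frames), fps=fps,
                       subject_id=params.subject_id)
    # pause interval is half-open: the first post-turn heel strike lands at
    # turn_end exactly and must survive the inclusive exclusion rule
    truth = GroundTruth(
        left=truth_feet["left"],
        right=truth_feet["right"],
        turn_start_frame=_frame(turn_start, fps),
        turn_end_frame=_frame(turn_end, fps) - 1,
        params=params,
    )
    return seq, truth


def ground_truth_features(
    gt: GroundTruth,
    schema: str = "per_foot",
    step_time_convention: str = "paper",
    label: str | None = None,
) -> GaitFeatureRow:
    """Feature row from the TRUE event frames — the recovery target for
    end-to-end tests.  Uses the same pairing and cadence definitions as the
    detection pipeline, applied to the true events and true turning window."""
    window = gt.turning_window() if gt.params.turn_pause > 0 else None
    return build_feature_row(
        (gt.event_series("left", "heel_strike"), gt.event_series("left", "toe_off")),
        (gt.event_series("right", "heel_strike"), gt.event_series("right", "toe_off")),
        window,
        gt.params.fps,
        schema="per_foot",
        step_time_convention=step_time_convention,
        subject_id=gt.params.subject_id,
        label=label,
    )


@dataclass
class ClassGaitStats:
    """Per-class feature distribution (means/SDs; times in s, cadence in
    steps/min)."""

    stride_mean: float
    stride_sd: float
    step_mean: float
    step_sd: float
    stance_mean: float
    stance_sd: float
    cadence_mean: float
    cadence_sd: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")


#: Faller contrasts observed in elderly gait: longer stance and stride times,
#: higher cadence, shorter step time, wider stride-time variability.
DEFAULT_FALLER_STATS = ClassGaitStats(
    stride_mean=1.12, stride_sd=0.10,
    step_mean=0.48, step_sd=0.04,
    stance_mean=0.72, stance_sd=0.06,
    cadence_mean=115.0, cadence_sd=8.0,
)

DEFAULT_NONFALLER_STATS = ClassGaitStats(
    stride_mean=1.06, stride_sd=0.05,
    step_mean=0.53, step_sd=0.03,
    stance_mean=0.66, stance_sd=0.04,
    cadence_mean=108.0, cadence_sd=6.0,
)


@dataclass
class PopulationParams:
    """Study-population parameters for synthetic feature tables.

    Default counts mirror the study composition: 44 fallers (elderly POMA
    cohort) and 21 non-fallers (healthy controls).
    """

    n_fallers: int = 44
    n_nonfallers: int = 21
    faller: ClassGaitStats = field(default_factory=lambda: DEFAULT_FALLER_STATS)
    nonfaller: ClassGaitStats = field(default_factory=lambda: DEFAULT_NONFALLER_STATS)
    asymmetry_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fallers <= 0 or self.n_nonfallers <= 0:
            raise ParameterError("class counts must be positive")

    @staticmethod
    def null(n_per_class: int = 32, seed: int = 0) -> "PopulationParams":
        """Zero class separation: both classes drawn from the same pooled
        distribution, balanced counts (for leakage checks)."""
        pooled = ClassGaitStats(
            stride_mean=1.09, stride_sd=0.08,
            step_mean=0.50, step_sd=0.035,
            stance_mean=0.69, stance_sd=0.05,
            cadence_mean=111.0, cadence_sd=7.0,
        )
        return PopulationParams(
            n_fallers=n_per_class, n_nonfallers=n_per_class,
            faller=pooled, nonfaller=replace(pooled), seed=seed,
        )


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Truncated-normal draws with positive support."""
    a = (1e-6 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_feature_table(params: PopulationParams | None = None) -> pd.DataFrame:
    """Draw a labelled per-foot feature table from the class distributions.

    Left/right values of each timing feature are the subject's base draw plus
    a small independent asymmetry perturbation; cadence is a single draw.
    Rows carry ``subject_id``, ``label`` and ``provenance="synthetic"``.
    """
    params = params or PopulationParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    for label, stats, n in (
        ("faller", params.faller, params.n_fallers),
        ("non_faller", params.nonfaller, params.n_nonfallers),
    ):
        base = {
            "stride_time": _draw_positive(rng, stats.stride_mean, stats.stride_sd, n),
            "step_time": _draw_positive(rng, stats.step_mean, stats.step_sd, n),
            "stance_time": _draw_positive(rng, stats.stance_mean, stats.stance_sd, n),
        }
        cad = _draw_positive(rng, stats.cadence_mean, stats.cadence_sd, n)
        for i in range(n):
            row = {"subject_id": f"{label}_{i:03d}"}
            for feat, vals in base.items():
                asym = rng.normal(0.0, params.asymmetry_sd)
                row[f"left_{feat}"] = max(vals[i] + asym / 2, 1e-3)
                row[f"right_{feat}"] = max(vals[i] - asym / 2, 1e-3)
            row["cadence"] = cad[i]
            row["label"] = label
            row["provenance"] = "synthetic"
            rows.append(row)
    cols = ["subject_id",
            "left_stride_time", "right_stride_time",
            "left_step_time", "right_step_time",
            "left_stance_time", "right_stance_time",
            "cadence", "label", "provenance"]
    return pd.DataFrame(rows)[cols]
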