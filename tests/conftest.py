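import json

import numpy as np
import pandas as pd
import pytest

import gaitfall as gf


@pytest.fixture(scope="session")
def sim_noiseless():
    """One deterministic noiseless TUG walk with ground truth."""
    return gf.simulate_tug(gf.GaitSimParams(seed=1))


@pytest.fixture(scope="session")
def detected_events(sim_noiseless):
    seq, _ = sim_noiseless
    return gf.detect_all_events(seq)


@pytest.fixture(scope="session")
def feature_table():
    """Default synthetic study population: 44 fallers / 21 non-fallers."""
    return gf.simulate_feature_table(gf.PopulationParams(seed=0))


@pytest.fixture()
def pose_json(tmp_path):
    """Factory for small AlphaPose-dialect JSON files."""

    def make(records, name="pose.json"):
        path = tmp_path / name
        path.write_text(json.dumps(records))
        return path

    return make


def make_detection(frame, y=500.0, conf=0.9, x=400.0):
    """One flat 26-keypoint detection record."""
    kps = []
    for _ in gf.HALPE26_KEYPOINTS:
        kps.extend([x, y, conf])
    return {"image_id": f"{frame}.jpg", "keypoints": kps, "score": conf}


def savgol_oracle(values, window_length, polyorder):
    """Independent brute-force Savitzky–Golay: per-sample least-squares
    polynomial fit over the (truncated near the edges) centred window."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    k = window_length // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        x = np.arange(lo, hi)
        deg = min(polyorder, len(x) - 1)
        coeffs = np.polynomial.polynomial.polyfit(x - i, values[lo:hi], deg)
        out[i] = coeffs[0]
    return out


def peak_oracle(values, min_distance):
    """Exhaustive O(n^2) peak finder: strict local maxima (plateaus at their
    first sample), then repeatedly keep the highest remaining candidate
    (ties: earliest) and discard all candidates closer than min_distance."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    cands = []
    for i in range(1, n - 1):
        if values[i] <= values[i - 1]:
            continue
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if j + 1 < n and values[j + 1] < values[i]:
            cands.append(i)
    kept = []
    remaining = list(cands)
    while remaining:
        best = max(remaining, key=lambda c: (values[c], -c))
        kept.append(best)
        remaining = [c for c in remaining if abs(c - best) >= min_distance and c != best]
    return sorted(kept)


def pipeline_feature_row(seq, **kwargs):
    """Full detection pipeline on one sequence: events -> turn -> features."""
    events = gf.detect_all_events(seq)
    window = gf.compute_turning_window(
        events[("left", "heel_strike")], events[("right", "heel_strike")])
    return gf.build_feature_row(
        (events[("left", "heel_strike")], events[("left", "toe_off")]),
        (events[("right", "heel_strike")], events[("right", "toe_off")]),
        window, seq.fps, **kwargs,
    ), window, events
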