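"""Velocity/acceleration-threshold (I-VT) gaze event classification.

Pixel gaze traces are converted to visual angle, differentiated after local
polynomial smoothing, and each sample is labelled *saccade* when the angular
speed exceeds 30 deg/s or the absolute tangential acceleration exceeds
8000 deg/s^2 — the default criterion of research-grade video eye trackers —
and *fixation* otherwise.  Blink/missing intervals override both labels.

Event post-processing (minimum saccade and fixation durations, blink padding)
follows common practice for 1000 Hz data; all thresholds are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .traces import GazeTrace, ScreenGeometry

#: I-VT defaults: speed and absolute tangential acceleration thresholds.
VELOCITY_THRESHOLD_DEG_S = 30.0
ACCEL_THRESHOLD_DEG_S2 = 8000.0

EVENT_COLUMNS = ["kind", "t_start", "t_end", "centroid_x", "centroid_y",
                 "amplitude_px"]


@dataclass
class AngularPosition:
    """Per-sample gaze direction in degrees, screen centre at (0, 0)."""

    t0: float
    sample_rate: float
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray


@dataclass
class KinematicSeries:
    """Angular speed (deg/s) and tangential acceleration (deg/s^2)."""

    t0: float
    sample_rate: float
    velocity: np.ndarray
    acceleration: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return self.velocity.size


def pixels_to_degrees(trace: GazeTrace, screen: ScreenGeometry) -> AngularPosition:
    """Convert pixel gaze to visual angle via the arctangent of the centred
    physical offset over the viewing distance.

    The screen centre maps to (0 deg, 0 deg); x is positive rightward and y
    positive downward, inheriting the pixel convention.
    """
    cx, cy = screen.center_px
    dx_cm = (trace.x - cx) * screen.pitch_x_cm
    dy_cm = (trace.y - cy) * screen.pitch_y_cm
    x_deg = np.degrees(np.arctan2(dx_cm, screen.viewing_distance_cm))
    y_deg = np.degrees(np.arctan2(dy_cm, screen.viewing_distance_cm))
    return AngularPosition(trace.t0, trace.sample_rate, x_deg, y_deg,
                           trace.valid.copy())


def degrees_per_pixel(screen: ScreenGeometry) -> float:
    """Small-angle conversion factor at screen centre (deg per pixel)."""
    pitch = 0.5 * (screen.pitch_x_cm + screen.pitch_y_cm)
    return float(np.degrees(np.arctan2(pitch, screen.viewing_distance_cm)))


def _valid_runs(valid: np.ndarray):
    """Maximal runs of True as (start, stop) half-open index pairs."""
    if valid.size == 0:
        return []
    padded = np.concatenate(([False], valid, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def estimate_kinematics(angles: AngularPosition, window: int = 9,
                        polyorder: int = 2) -> KinematicSeries:
    """Smooth the 2-D angular trajectory with a local least-squares
    polynomial (Savitzky-Golay), then differentiate.

    Speed is the magnitude of the angular velocity vector; acceleration is the
    (signed) time derivative of that speed.  Each maximal valid run is
    processed independently; runs shorter than the smoothing window, and a
    half-window margin adjacent to invalid runs, are marked invalid.
    """
    n = angles.x_deg.size
    fs = angles.sample_rate
    dt = 1.0 / fs
    velocity = np.full(n, np.nan)
    acceleration = np.full(n, np.nan)
    kin_valid = np.zeros(n, dtype=bool)
    half = window // 2

    for start, stop in _valid_runs(angles.valid):
        m = stop - start
        if m < window:
            continue  # too short to smooth -> stays invalid
        xs = savgol_filter(angles.x_deg[start:stop], window, polyorder,
                           mode="interp")
        ys = savgol_filter(angles.y_deg[start:stop], window, polyorder,
                           mode="interp")
        vx = np.gradient(xs, dt)
        vy = np.gradient(ys, dt)
        speed = np.hypot(vx, vy)
        acc = np.gradient(speed, dt)
        velocity[start:stop] = speed
        acceleration[start:stop] = acc
        kin_valid[start:stop] = True
        # erode run edges that abut invalid data (not true trace boundaries)
        if start > 0:
            kin_valid[start:start + half + 1] = False
        if stop < n:
            kin_valid[max(start, stop - half - 1):stop] = False

    return KinematicSeries(angles.t0, fs, velocity, acceleration, kin_valid)


def detect_blinks(trace: GazeTrace, pad: float = 0.05) -> list[tuple[float, float]]:
    """Maximal invalid runs extended by ``pad`` seconds on both sides, merged
    when padding makes them overlap.  Returned intervals are clipped to the
    trace extent."""
    fs = trace.sample_rate
    t_end_trace = trace.t0 + trace.x.size / fs
    intervals = []
    for start, stop in _valid_runs(~trace.valid):
        a = max(trace.t0, trace.t0 + start / fs - pad)
        b = min(t_end_trace, trace.t0 + stop / fs + pad)
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((a, b))
    return intervals


def _label_runs(labels: np.ndarray):
    """Runs of equal label as (start, stop, label)."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    return [(bounds[i], bounds[i + 1], int(labels[bounds[i]]))
            for i in range(bounds.size - 1)]


_INVALID, _FIX, _SACC = -1, 0, 1


def classify_events(kin: KinematicSeries, blinks: list[tuple[float, float]],
                    trace: GazeTrace,
                    velocity_threshold: float = VELOCITY_THRESHOLD_DEG_S,
                    accel_threshold: float = ACCEL_THRESHOLD_DEG_S2,
                    min_saccade: float = 0.008,
                    min_fixation: float = 0.050) -> pd.DataFrame:
    """Classify samples and aggregate them into fixation/saccade/blink events.

    A valid sample is a saccade sample iff speed > ``velocity_threshold`` or
    |acceleration| > ``accel_threshold`` (strict, per the "exceeding"
    convention), otherwise a fixation sample.  Contiguous same-label runs
    become events; saccade runs shorter than ``min_saccade`` are relabelled
    fixation, then fixation runs shorter than ``min_fixation`` are absorbed
    into the longer neighbouring event.  Blink intervals override both.

    Returns a DataFrame with columns ``kind, t_start, t_end, centroid_x,
    centroid_y, amplitude_px`` sorted by onset.  Fixation centroids are the
    mean member pixel position; saccade amplitude is the Euclidean pixel
    distance between the last pre-saccade and first post-saccade positions.
    """
    n = len(kin)
    fs = kin.sample_rate
    t0 = kin.t0
    labels = np.full(n, _INVALID, dtype=np.int8)

    usable = kin.valid.copy()
    for a, b in blinks:  # blink (incl. padding) overrides everything
        sl = slice(max(0, int(round((a - t0) * fs))),
                   min(n, int(round((b - t0) * fs))))
        usable[sl] = False
    sacc = (kin.velocity > velocity_threshold) | \
           (np.abs(kin.acceleration) > accel_threshold)
    labels[usable] = np.where(sacc[usable], _SACC, _FIX)

    min_sacc_n = max(1, int(round(min_saccade * fs)))
    min_fix_n = max(1, int(round(min_fixation * fs)))

    # work segment-by-segment over maximal usable runs
    events = []
    for seg_start, seg_stop in _valid_runs(usable):
        seg = labels[seg_start:seg_stop].copy()
        runs = _label_runs(seg)
        # pass 1: short saccades -> fixation
        changed = True
        while changed:
            changed = False
            runs = _label_runs(seg)
            for a, b, lab in runs:
                if lab == _SACC and (b - a) < min_sacc_n:
                    seg[a:b] = _FIX
                    changed = True
        # pass 2: short fixations -> absorbed into the longer neighbour
        changed = True
        while changed:
            changed = False
            runs = _label_runs(seg)
            for idx, (a, b, lab) in enumerate(runs):
                if lab != _FIX or (b - a) >= min_fix_n:
                    continue
                left = runs[idx - 1] if idx > 0 else None
                right = runs[idx + 1] if idx + 1 < len(runs) else None
                if left is None and right is None:
                    continue  # isolated short fixation: keep
                nb = max((r for r in (left, right) if r is not None),
                         key=lambda r: r[1] - r[0])
                seg[a:b] = nb[2]
                changed = True
                break
        for a, b, lab in _label_runs(seg):
            i, j = seg_start + a, seg_start + b
            ev = {
                "kind": "fixation" if lab == _FIX else "saccade",
                "t_start": t0 + i / fs,
                "t_end": t0 + j / fs,
                "centroid_x": np.nan, "centroid_y": np.nan,
                "amplitude_px": np.nan,
            }
            if lab == _FIX:
                ev["centroid_x"] = float(np.mean(trace.x[i:j]))
                ev["centroid_y"] = float(np.mean(trace.y[i:j]))
            else:
                # last pre-saccade / first post-saccade positions (fall back
                # to the run's own endpoints at segment edges)
                pre = i - 1 if i - 1 >= seg_start else i
                post = j if j < seg_stop else j - 1
                ev["amplitude_px"] = float(np.hypot(
                    trace.x[post] - trace.x[pre],
                    trace.y[post] - trace.y[pre]))
            events.append(ev)

    for a, b in blinks:
        events.append({"kind": "blink", "t_start": a, "t_end": b,
                       "centroid_x": np.nan, "centroid_y": np.nan,
                       "amplitude_px": np.nan})

    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return df.sort_values("t_start", kind="stable").reset_index(drop=True)


def detect_gaze_events(trace: GazeTrace, screen: ScreenGeometry,
                       blink_pad: float = 0.05, **classify_kwargs) -> pd.DataFrame:
    """Convenience pipeline: angles -> kinematics -> blinks -> events."""
    angles = pixels_to_degrees(trace, screen)
    kin = estimate_kinematics(angles)
    blinks = detect_blinks(trace, pad=blink_pad)
    return classify_events(kin, blinks, trace, **classify_kwargs)
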