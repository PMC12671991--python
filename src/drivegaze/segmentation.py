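"""Derive the 4-s Lo/Hi/Baseline analysis windows of each trial from
telemetry.

Per trial the three windows are:

* **Lo** (Coasting/Following) — the 4-s window with the least control
  variation over a task-specific span: gas for the traffic-light task,
  gas+steering for the steering task, steering over the pre-brake span for
  the lead-car task.  "Least variation" is the sum over channels of the
  within-window variance normalized by that channel's variance over the whole
  search span.
* **Hi** (Braking/Steering) — the 4 s beginning at the onset of the braking
  (or steering) response: the earliest time at which the control magnitude
  stays above threshold for a minimum hold.
* **Baseline** — seconds 4–8 of the 9-s rest period that follows the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import TaskKind, TrialSchedule
from .traces import TelemetryTrace

WINDOW_COLUMNS = ["trial_id", "label", "t_start", "t_end"]
WINDOW_LEN = 4.0


@dataclass(frozen=True)
class OnsetSpec:
    """Threshold rule for a control-response onset."""

    channel: str = "brake"
    threshold: float = 0.05
    min_hold: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_hold < 0:
            raise ValueError("min_hold must be non-negative")


def detect_control_onset(trace: TelemetryTrace, spec: OnsetSpec,
                         search: tuple[float, float]) -> float | None:
    """Earliest time in ``search`` at which |channel| >= threshold
    continuously for ``min_hold`` seconds; None if no qualifying crossing."""
    a, b = search
    if b <= a:
        raise ValueError("empty search interval")
    if a < trace.t0 - 1e-9 or b > trace.t0 + trace.duration + 1e-9:
        raise ValueError("search interval outside trace extent")
    x = np.abs(trace.channel(spec.channel))
    fs = trace.sample_rate
    i0 = max(0, int(round((a - trace.t0) * fs)))
    i1 = min(len(trace), int(round((b - trace.t0) * fs)))
    hold = max(1, int(round(spec.min_hold * fs)))
    above = x >= spec.threshold
    # sustained[i] == True iff above[i:i+hold] all True (hold fits in trace)
    if len(trace) < hold:
        return None
    window_ok = np.convolve(above.astype(np.int32), np.ones(hold, dtype=np.int32),
                            mode="valid") == hold
    for i in range(i0, min(i1, window_ok.size)):
        if window_ok[i]:
            return float(trace.t0 + i / fs)
    return None


def find_min_variation_window(trace: TelemetryTrace, channels: list[str],
                              search: tuple[float, float],
                              window_len: float = WINDOW_LEN
                              ) -> tuple[float, float]:
    """Offset (on the telemetry sample grid) minimizing the normalized
    variance score; ties break toward the earliest offset.

    Score at offset i = sum over channels of var(channel[i:i+L]) divided by
    the channel's variance over the whole search span (channels with zero
    search-span variance contribute 0).
    """
    a, b = search
    fs = trace.sample_rate
    if b - a < window_len - 1e-9:
        raise ValueError("search interval shorter than window length")
    i0 = max(0, int(round((a - trace.t0) * fs)))
    i1 = min(len(trace), int(round((b - trace.t0) * fs)))
    L = int(round(window_len * fs))
    n_off = i1 - i0 - L + 1
    if n_off < 1:
        raise ValueError("search interval shorter than window length")

    score = np.zeros(n_off)
    for name in channels:
        x = trace.channel(name)[i0:i1].astype(float)
        total_var = float(np.var(x))
        if total_var == 0.0:
            continue
        c1 = np.concatenate(([0.0], np.cumsum(x)))
        c2 = np.concatenate(([0.0], np.cumsum(x * x)))
        s1 = c1[L:] - c1[:-L]
        s2 = c2[L:] - c2[:-L]
        var = np.maximum(s2 / L - (s1 / L) ** 2, 0.0)
        score += var / total_var
    best = int(np.argmin(score))  # argmin returns the earliest tie
    t_start = trace.t0 + (i0 + best) / fs
    return t_start, t_start + window_len


@dataclass(frozen=True)
class TaskRules:
    """Task-specific segmentation configuration."""

    accel_duration: float = 3.0   # span excluded after trial start (s)
    brake_threshold: float = 0.05
    steer_threshold: float = 0.05
    min_hold: float = 0.1
    lo_lookback: float = 8.0      # lead-car pre-brake search span (s)
    window_len: float = WINDOW_LEN
    baseline_offset: float = 4.0  # baseline = rest_start + [4, 8) s

    def onset_spec(self, task: TaskKind) -> OnsetSpec:
        if task is TaskKind.UNANTICIPATED_STEERING:
            return OnsetSpec("steering", self.steer_threshold, self.min_hold)
        return OnsetSpec("brake", self.brake_threshold, self.min_hold)

    def lo_channels(self, task: TaskKind) -> list[str]:
        return {
            TaskKind.TRAFFIC_LIGHT_BRAKING: ["gas"],
            TaskKind.UNANTICIPATED_STEERING: ["gas", "steering"],
            TaskKind.LEAD_CAR_BRAKING: ["steering"],
        }[task]


@dataclass
class SegmentationResult:
    windows: pd.DataFrame
    flags: list[tuple[int, str]] = field(default_factory=list)


def build_windows(trial: TrialSchedule, telemetry: TelemetryTrace,
                  rules: TaskRules = TaskRules()) -> SegmentationResult:
    """Lo/Hi/Baseline windows for one trial.  A missing response onset or a
    too-short Lo span omits the window and raises a flag."""
    task = trial.task
    rows, flags = [], []
    w = rules.window_len

    if task is TaskKind.LEAD_CAR_BRAKING:
        lo_search = (max(trial.t_start, trial.t_event - rules.lo_lookback),
                     trial.t_event)
    else:
        lo_search = (trial.t_start + rules.accel_duration, trial.t_event)
    if lo_search[1] - lo_search[0] >= w:
        t_lo, t_lo_end = find_min_variation_window(
            telemetry, rules.lo_channels(task), lo_search, w)
        rows.append((trial.trial_id, "Lo", t_lo, t_lo_end))
    else:
        flags.append((trial.trial_id, "lo-span-too-short"))

    onset = detect_control_onset(telemetry, rules.onset_spec(task),
                                 (trial.t_event, trial.t_rest_start))
    if onset is not None and onset + w <= telemetry.t0 + telemetry.duration:
        rows.append((trial.trial_id, "Hi", onset, onset + w))
    else:
        flags.append((trial.trial_id, "no-response-onset"))

    b0 = trial.t_rest_start + rules.baseline_offset
    rows.append((trial.trial_id, "Baseline", b0, b0 + w))

    return SegmentationResult(
        pd.DataFrame(rows, columns=WINDOW_COLUMNS), flags)


def build_all_windows(schedule: list[TrialSchedule],
                      telemetry: TelemetryTrace,
                      rules: TaskRules = TaskRules()) -> SegmentationResult:
    """Windows for every trial of a session, concatenated."""
    frames, flags = [], []
    for trial in schedule:
        res = build_windows(trial, telemetry, rules)
        frames.append(res.windows)
        flags.extend(res.flags)
    windows = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=WINDOW_COLUMNS))
    return SegmentationResult(windows, flags)
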