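"""Readers and writers for the delimited-text interchange formats.

Gaze is ``t_s,x_px,y_px,valid`` (floats at full precision, so a write->read
round trip is bit-identical); telemetry is ``t_s,gas,brake,steering,speed``;
windows, events, metrics and comparison tables are plain CSV with documented
headers; schedules and ground truth go to JSON.  A minimal EyeLink-ASC-like
dialect (tab-separated sample lines, ``.`` for missing coordinates, event
lines such as SFIX/ESACC that are ignored on read — events are always
recomputed, never trusted) is supported for round-trip testing against
tracker-style exports.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .errors import FormatError
from .events import EVENT_COLUMNS
from .metrics import METRIC_COLUMNS
from .segmentation import WINDOW_COLUMNS
from .simulate import TaskKind, TrialSchedule
from .traces import GazeTrace, NeuralTrace, TelemetryTrace

_FLOAT_FMT = "%.17g"


def _infer_grid(t: np.ndarray) -> tuple[float, float]:
    """(t0, sample_rate) from strictly increasing timestamps."""
    if t.size == 0:
        raise FormatError("no samples")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("timestamps must be strictly increasing")
        return float(t[0]), float(1.0 / np.median(dt))
    return float(t[0]), 1000.0


# -- gaze --------------------------------------------------------------------

def write_gaze_csv(trace: GazeTrace, path) -> None:
    data = np.column_stack([trace.t, trace.x, trace.y,
                            trace.valid.astype(float)])
    with open(path, "w") as f:
        f.write("t_s,x_px,y_px,valid\n")
        np.savetxt(f, data, fmt=[_FLOAT_FMT] * 3 + ["%d"], delimiter=",")


def write_gaze_asc(trace: GazeTrace, path, events: pd.DataFrame | None = None
                   ) -> None:
    """Minimal tracker-style export: millisecond sample lines plus optional
    SFIX/EFIX/SSACC/ESACC event lines."""
    ev_lines: list[tuple[float, str]] = []
    if events is not None:
        for r in events.itertuples():
            ms0, ms1 = r.t_start * 1000.0, r.t_end * 1000.0
            if r.kind == "fixation":
                ev_lines.append((ms0, f"SFIX L {ms0:.3f}"))
                ev_lines.append((ms1, f"EFIX L {ms0:.3f} {ms1:.3f} "
                                      f"{ms1 - ms0:.3f} {r.centroid_x:.2f} "
                                      f"{r.centroid_y:.2f}"))
            elif r.kind == "saccade":
                ev_lines.append((ms0, f"SSACC L {ms0:.3f}"))
                ev_lines.append((ms1, f"ESACC L {ms0:.3f} {ms1:.3f} "
                                      f"{ms1 - ms0:.3f} {r.amplitude_px:.2f}"))
    ev_lines.sort(key=lambda e: e[0])
    k = 0
    with open(path, "w") as f:
        f.write(f"** RATE {trace.sample_rate:.2f}\n")
        f.write("MSG 0 SYNTHETIC\n")
        for i in range(len(trace)):
            ms = (trace.t0 + i / trace.sample_rate) * 1000.0
            while k < len(ev_lines) and ev_lines[k][0] <= ms:
                f.write(ev_lines[k][1] + "\n")
                k += 1
            if trace.valid[i]:
                f.write(f"{ms:.3f}\t{trace.x[i]:.4f}\t{trace.y[i]:.4f}\t0.0\n")
            else:
                f.write(f"{ms:.3f}\t.\t.\t0.0\n")
        for _, line in ev_lines[k:]:
            f.write(line + "\n")


def _read_gaze_csv(path) -> GazeTrace:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot parse gaze file {path}: {e}") from e
    expected = ["t_s", "x_px", "y_px", "valid"]
    if list(df.columns) != expected or len(df) == 0:
        raise FormatError(f"gaze file {path} must have columns {expected} "
                          "and at least one sample")
    t0, fs = _infer_grid(df["t_s"].to_numpy(float))
    return GazeTrace(t0, fs, df["x_px"].to_numpy(float),
                     df["y_px"].to_numpy(float),
                     df["valid"].to_numpy(float) > 0.5)


def _read_gaze_asc(path) -> GazeTrace:
    t_ms, xs, ys = [], [], []
    with open(path) as f:
        for line in f:
            tok = line.split()
            if not tok:
                continue
            try:
                ts = float(tok[0])
            except ValueError:
                continue  # event/message line: ignored, events are recomputed
            if len(tok) < 3:
                raise FormatError(f"malformed sample line in {path}: {line!r}")
            t_ms.append(ts)
            if tok[1] == "." or tok[2] == ".":
                xs.append(np.nan)
                ys.append(np.nan)
            else:
                xs.append(float(tok[1]))
                ys.append(float(tok[2]))
    t = np.asarray(t_ms) / 1000.0
    t0, fs = _infer_grid(t)
    x = np.asarray(xs)
    y = np.asarray(ys)
    return GazeTrace(t0, fs, x, y, ~np.isnan(x))


def read_gaze(path, dialect: str = "csv") -> GazeTrace:
    if dialect == "csv":
        return _read_gaze_csv(path)
    if dialect == "asc-min":
        return _read_gaze_asc(path)
    raise ValueError(f"unknown gaze dialect {dialect!r}")


# -- telemetry ---------------------------------------------------------------

def write_telemetry_csv(trace: TelemetryTrace, path) -> None:
    data = np.column_stack([trace.t, trace.gas, trace.brake,
                            trace.steering, trace.speed])
    with open(path, "w") as f:
        f.write("t_s,gas,brake,steering,speed\n")
        np.savetxt(f, data, fmt=_FLOAT_FMT, delimiter=",")


def read_telemetry(path) -> TelemetryTrace:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot parse telemetry file {path}: {e}") from e
    expected = ["t_s", "gas", "brake", "steering", "speed"]
    if list(df.columns) != expected or len(df) == 0:
        raise FormatError(f"telemetry file {path} must have columns "
                          f"{expected}")
    t0, fs = _infer_grid(df["t_s"].to_numpy(float))
    return TelemetryTrace(t0, fs, df["gas"].to_numpy(float),
                          df["brake"].to_numpy(float),
                          df["steering"].to_numpy(float),
                          df["speed"].to_numpy(float))


# -- neural ------------------------------------------------------------------

def write_neural_csv(trace: NeuralTrace, path) -> None:
    t = trace.t0 + np.arange(len(trace)) / trace.sample_rate
    with open(path, "w") as f:
        f.write("t_s,amplitude\n")
        np.savetxt(f, np.column_stack([t, trace.samples]), fmt=_FLOAT_FMT,
                   delimiter=",")


def read_neural(path) -> NeuralTrace:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot parse neural file {path}: {e}") from e
    if list(df.columns) != ["t_s", "amplitude"] or len(df) == 0:
        raise FormatError(f"neural file {path} must have columns "
                          "['t_s', 'amplitude']")
    t0, fs = _infer_grid(df["t_s"].to_numpy(float))
    return NeuralTrace(fs, df["amplitude"].to_numpy(float), t0)


# -- tables ------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, columns: list[str] | None = None
                ) -> None:
    out = df if columns is None else df[columns]
    out.to_csv(path, index=False)


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(WINDOW_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"windows file {path} lacks columns {missing}")
    return df


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events file {path} lacks columns {missing}")
    return df


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metrics file {path} lacks columns {missing}")
    return df


# -- schedules ---------------------------------------------------------------

def write_schedule(schedule: list[TrialSchedule], path) -> None:
    payload = []
    for tr in schedule:
        d = asdict(tr)
        d["task"] = tr.task.value
        payload.append(d)
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def read_schedule(path) -> list[TrialSchedule]:
    with open(path) as f:
        payload = json.load(f)
    return [TrialSchedule(task=TaskKind(d["task"]), trial_id=d["trial_id"],
                          t_start=d["t_start"], t_event=d["t_event"],
                          t_rest_start=d["t_rest_start"],
                          t_rest_end=d["t_rest_end"])
            for d in payload]
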