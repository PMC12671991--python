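"""Scene-independent gaze metrics per 4-s analysis window, plus the
missing-data exclusion rule.

The seven metrics — fixation count, mean fixation duration, mean horizontal
and vertical gaze position, mean saccade amplitude, and horizontal/vertical
spread of search — need no predefined areas of interest.  Events are assigned
to a window by onset time and fixation durations are not clipped at window
edges, making the fixation count a renewal count with a closed-form
expectation.  Spread of search is the sample (n-1) SD of valid gaze samples
per axis.  Windows with more than ``max_missing`` (default 20%) missing
samples are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .traces import GazeTrace

METRIC_COLUMNS = [
    "trial_id", "label", "fixation_count", "fixation_duration_ms",
    "mean_gaze_x", "mean_gaze_y", "saccade_amplitude_px",
    "spread_x", "spread_y", "missing_fraction",
]

#: the seven metrics, in canonical reporting order
METRIC_ORDER = [
    "fixation_count", "fixation_duration_ms", "mean_gaze_x", "mean_gaze_y",
    "spread_x", "spread_y", "saccade_amplitude_px",
]

METRIC_UNITS = {
    "fixation_count": "#",
    "fixation_duration_ms": "ms",
    "mean_gaze_x": "pxls",
    "mean_gaze_y": "pxls",
    "spread_x": "pxls",
    "spread_y": "pxls",
    "saccade_amplitude_px": "pxls",
}


def compute_window_metrics(events: pd.DataFrame, trace: GazeTrace,
                           window) -> dict:
    """Metrics for one window.

    ``window`` is any mapping/row with ``trial_id, label, t_start, t_end``.
    Raises ValueError when the window lies outside the trace; with zero valid
    samples the metrics are NaN and ``missing_fraction`` is 1.
    """
    w = window if isinstance(window, dict) else dict(window)
    t_start, t_end = float(w["t_start"]), float(w["t_end"])
    sl = trace.sample_slice(t_start, t_end)
    if sl.start < 0 or sl.stop > len(trace) or sl.stop <= sl.start:
        raise ValueError("window outside trace extent")

    valid = trace.valid[sl]
    n_total = sl.stop - sl.start
    n_valid = int(valid.sum())
    missing = 1.0 - n_valid / n_total

    out = {
        "trial_id": w.get("trial_id", -1), "label": w.get("label", ""),
        "fixation_count": np.nan, "fixation_duration_ms": np.nan,
        "mean_gaze_x": np.nan, "mean_gaze_y": np.nan,
        "saccade_amplitude_px": np.nan,
        "spread_x": np.nan, "spread_y": np.nan,
        "missing_fraction": missing, "n_valid_samples": n_valid,
    }
    if n_valid == 0:
        return out

    x = trace.x[sl][valid]
    y = trace.y[sl][valid]
    out["mean_gaze_x"] = float(np.mean(x))
    out["mean_gaze_y"] = float(np.mean(y))
    out["spread_x"] = float(np.std(x, ddof=1)) if n_valid > 1 else 0.0
    out["spread_y"] = float(np.std(y, ddof=1)) if n_valid > 1 else 0.0

    onset_in = (events["t_start"] >= t_start) & (events["t_start"] < t_end)
    fix = events[(events["kind"] == "fixation") & onset_in]
    sac = events[(events["kind"] == "saccade") & onset_in]
    out["fixation_count"] = int(len(fix))
    if len(fix):
        out["fixation_duration_ms"] = float(
            (fix["t_end"] - fix["t_start"]).mean() * 1000.0)
    if len(sac):
        out["saccade_amplitude_px"] = float(sac["amplitude_px"].mean())
    return out


def compute_metrics_table(events: pd.DataFrame, trace: GazeTrace,
                          windows: pd.DataFrame) -> pd.DataFrame:
    """One metrics row per window."""
    rows = [compute_window_metrics(events, trace, row)
            for _, row in windows.iterrows()]
    cols = METRIC_COLUMNS + ["n_valid_samples"]
    return pd.DataFrame(rows, columns=cols)


def apply_exclusion(metrics: pd.DataFrame, max_missing: float = 0.20
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition windows into (retained, excluded).

    A window is excluded iff its missing fraction is strictly greater than
    ``max_missing`` ("more than 20% missing"); exactly 20% is retained.
    """
    keep = metrics["missing_fraction"] <= max_missing
    return metrics[keep].copy(), metrics[~keep].copy()
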