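"""Onset detection, minimum-variation search, and window construction."""

import numpy as np
import pandas as pd
import pytest

from drivegaze import (OnsetSpec, TaskKind, TaskRules, TelemetryParams,
                       TelemetryTrace, build_all_windows, build_windows,
                       detect_control_onset, find_min_variation_window,
                       generate_task_schedule, generate_telemetry)


def _trace(brake=None, gas=None, steering=None, fs=60.0, n=1200):
    z = np.zeros(n)
    return TelemetryTrace(0.0, fs,
                          z if gas is None else gas,
                          z if brake is None else brake,
                          z if steering is None else steering, z)


# -- detect_control_onset ----------------------------------------------------

def test_onset_of_planted_ramp():
    fs = 60.0
    n = 1200
    t = np.arange(n) / fs
    brake = np.clip((t - 12.0) / 0.25, 0.0, 1.0) * 0.8
    trace = _trace(brake=brake)
    onset = detect_control_onset(trace, OnsetSpec("brake", 0.05, 0.1),
                                 (8.0, 18.0))
    assert onset == pytest.approx(12.0, abs=1.0 / fs + 1e-9)


def test_all_zero_channel_gives_none():
    assert detect_control_onset(_trace(), OnsetSpec("brake", 0.05, 0.1),
                                (0.0, 10.0)) is None


def test_channel_above_threshold_from_start():
    trace = _trace(brake=np.full(1200, 0.5))
    onset = detect_control_onset(trace, OnsetSpec("brake", 0.05, 0.1),
                                 (3.0, 10.0))
    assert onset == pytest.approx(3.0)


def test_empty_search_interval_rejected():
    with pytest.raises(ValueError):
        detect_control_onset(_trace(), OnsetSpec(), (5.0, 5.0))


def test_hold_requirement_skips_transients():
    fs = 60.0
    brake = np.zeros(1200)
    brake[300:303] = 0.5            # 50 ms transient: too short for 100 ms
    brake[600:] = 0.5
    onset = detect_control_onset(_trace(brake=brake),
                                 OnsetSpec("brake", 0.05, 0.1), (0.0, 20.0))
    assert onset == pytest.approx(600 / fs)


# -- find_min_variation_window ----------------------------------------------

def _brute_force(trace, channels, search, window_len=4.0):
    """Independent exhaustive-offset oracle."""
    fs = trace.sample_rate
    i0 = int(round(search[0] * fs))
    i1 = int(round(search[1] * fs))
    L = int(round(window_len * fs))
    best, best_score = None, np.inf
    for i in range(i0, i1 - L + 1):
        score = 0.0
        for name in channels:
            x = trace.channel(name)[i0:i1]
            tv = np.var(x)
            if tv > 0:
                score += np.var(trace.channel(name)[i:i + L]) / tv
        if score < best_score - 1e-15:
            best, best_score = i, score
    return best / fs, best / fs + window_len


def test_noiseless_plateau_found_inside_noise():
    rng = np.random.default_rng(0)
    gas = rng.normal(0.3, 0.05, 1200)
    gas[400:700] = 0.35  # perfectly flat plateau
    trace = _trace(gas=gas)
    win = find_min_variation_window(trace, ["gas"], (0.0, 20.0))
    assert 400 / 60.0 <= win[0] and win[1] <= 700 / 60.0 + 1e-9
    assert win == pytest.approx(_brute_force(trace, ["gas"], (0.0, 20.0)))


def test_constant_channel_ties_break_earliest():
    trace = _trace(gas=np.full(1200, 0.4))
    win = find_min_variation_window(trace, ["gas"], (2.0, 18.0))
    assert win[0] == pytest.approx(2.0)
    assert win[1] - win[0] == pytest.approx(4.0)


def test_later_strictly_flatter_segment_wins():
    rng = np.random.default_rng(3)
    gas = rng.normal(0.3, 0.08, 1200)
    gas[180:450] = 0.3 + rng.normal(0, 0.01, 270)   # early, less flat
    gas[700:1000] = 0.3                              # later, perfectly flat
    trace = _trace(gas=gas)
    win = find_min_variation_window(trace, ["gas"], (0.0, 20.0))
    assert win[0] >= 700 / 60.0 - 1e-9
    assert win == pytest.approx(_brute_force(trace, ["gas"], (0.0, 20.0)))


def test_matches_brute_force_on_random_traces():
    """Oracle equivalence with an exhaustive scan over random multi-channel
    telemetry."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 900
        gas = rng.normal(0.3, 0.05, n) + 0.1 * np.sin(np.arange(n) / 40.0)
        steering = rng.normal(0.0, 0.02, n)
        trace = _trace(gas=gas, steering=steering, n=n)
        search = (1.0, n / 60.0 - 1.0)
        fast = find_min_variation_window(trace, ["gas", "steering"], search)
        slow = _brute_force(trace, ["gas", "steering"], search)
        assert fast == pytest.approx(slow)


def test_search_shorter_than_window_rejected():
    with pytest.raises(ValueError):
        find_min_variation_window(_trace(), ["gas"], (0.0, 3.0))


# -- build_windows -----------------------------------------------------------

def test_traffic_light_trial_windows():
    """Hi starts at the planted brake onset (within one telemetry sample);
    Baseline covers rest seconds 4-8."""
    sched = generate_task_schedule(TaskKind.TRAFFIC_LIGHT_BRAKING, 1, seed=4)
    tel = generate_telemetry(sched, seed=4)
    res = build_windows(sched[0], tel)
    w = res.windows.set_index("label")
    assert res.flags == []
    tr = sched[0]
    assert w.loc["Hi", "t_start"] == pytest.approx(
        tr.t_event, abs=2.0 / tel.sample_rate + 1e-9)
    assert w.loc["Baseline", "t_start"] == pytest.approx(tr.t_rest_start + 4)
    assert w.loc["Baseline", "t_end"] == pytest.approx(tr.t_rest_start + 8)
    for _, row in res.windows.iterrows():
        assert row["t_end"] - row["t_start"] == pytest.approx(4.0)


def test_missing_brake_flags_trial():
    sched = generate_task_schedule(TaskKind.TRAFFIC_LIGHT_BRAKING, 1, seed=4)
    tel = generate_telemetry(sched, seed=4)
    tel.brake[:] = 0.0  # driver never brakes
    res = build_windows(sched[0], tel)
    assert "Hi" not in set(res.windows["label"])
    assert res.flags == [(1, "no-response-onset")]


def test_steering_lo_window_inside_plateau():
    """With zero plateau noise the Lo window of a steering trial falls
    entirely inside the planted coasting plateau."""
    sched = generate_task_schedule(TaskKind.UNANTICIPATED_STEERING, 3, seed=9)
    params = TelemetryParams(plateau_noise_sd=0.0, steering_noise_sd=0.0)
    tel = generate_telemetry(sched, params, seed=9)
    res = build_all_windows(sched, tel)
    lo = res.windows[res.windows["label"] == "Lo"]
    for row, tr in zip(lo.itertuples(), sched):
        assert row.t_start >= tr.t_start + 3.0 - 1e-9
        assert row.t_end <= tr.t_event + 1e-9


def test_hi_never_precedes_event_on_noiseless_telemetry():
    for task in TaskKind:
        sched = generate_task_schedule(task, 4, seed=2)
        params = TelemetryParams(plateau_noise_sd=0.0, steering_noise_sd=0.0)
        tel = generate_telemetry(sched, params, seed=2)
        res = build_all_windows(sched, tel)
        hi = res.windows[res.windows["label"] == "Hi"].set_index("trial_id")
        for tr in sched:
            if tr.trial_id in hi.index:
                assert hi.loc[tr.trial_id, "t_start"] >= tr.t_event - 1e-9


def test_all_windows_are_four_seconds():
    for task in TaskKind:
        sched = generate_task_schedule(task, 5, seed=6)
        tel = generate_telemetry(sched, seed=6)
        res = build_all_windows(sched, tel)
        assert np.allclose(res.windows["t_end"] - res.windows["t_start"], 4.0)
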