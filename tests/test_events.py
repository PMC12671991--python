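"""Pixel-to-angle conversion, kinematic estimation and I-VT classification."""

import numpy as np
import pandas as pd
import pytest

from drivegaze import (GazeParams, GazeTrace, ScreenGeometry, classify_events,
                       detect_blinks, detect_gaze_events, estimate_kinematics,
                       generate_gaze, pixels_to_degrees)
from drivegaze.events import degrees_per_pixel
from tests.conftest import constant_gaze, tiled_params_windows

LEGACY_SCREEN = ScreenGeometry(1024, 768, 34.0, 25.5, 90.0)


# -- pixels_to_degrees -------------------------------------------------------

def test_screen_center_maps_to_zero(screen):
    cx, cy = screen.center_px
    trace = constant_gaze(0.01, cx, cy)
    ang = pixels_to_degrees(trace, screen)
    assert np.allclose(ang.x_deg, 0.0)
    assert np.allclose(ang.y_deg, 0.0)


def test_hand_trigonometry_100px():
    """100 px right of centre at 0.0332 cm/px pitch and 90 cm distance is
    arctan(3.32/90) = 2.11 deg."""
    trace = constant_gaze(0.01, 512.0 + 100.0, 384.0)
    ang = pixels_to_degrees(trace, LEGACY_SCREEN)
    expected = np.degrees(np.arctan2(100 * 34.0 / 1024, 90.0))
    assert ang.x_deg[0] == pytest.approx(expected, abs=1e-9)
    assert ang.x_deg[0] == pytest.approx(2.11, abs=0.005)


def test_mirrored_offsets_antisymmetric(screen):
    cx, cy = screen.center_px
    left = pixels_to_degrees(constant_gaze(0.01, cx - 250, cy + 80), screen)
    right = pixels_to_degrees(constant_gaze(0.01, cx + 250, cy - 80), screen)
    assert left.x_deg[0] == pytest.approx(-right.x_deg[0])
    assert left.y_deg[0] == pytest.approx(-right.y_deg[0])


def test_bad_geometry_rejected():
    with pytest.raises(ValueError):
        ScreenGeometry(width_px=-10)
    with pytest.raises(ValueError):
        ScreenGeometry(width_cm=10.0)  # anisotropic pitch


# -- estimate_kinematics -----------------------------------------------------

def _angles_from_deg(x_deg, fs=1000.0):
    n = x_deg.size
    from drivegaze.events import AngularPosition
    return AngularPosition(0.0, fs, x_deg, np.zeros(n),
                           np.ones(n, dtype=bool))


def test_constant_position_zero_kinematics():
    kin = estimate_kinematics(_angles_from_deg(np.full(500, 3.0)))
    assert np.allclose(kin.velocity[kin.valid], 0.0, atol=1e-9)
    assert np.allclose(kin.acceleration[kin.valid], 0.0, atol=1e-6)


def test_linear_ramp_velocity():
    """A noiseless 10 deg/s ramp yields velocity 10 deg/s in the interior."""
    t = np.arange(1000) / 1000.0
    kin = estimate_kinematics(_angles_from_deg(10.0 * t))
    interior = kin.velocity[10:-10]
    assert np.allclose(interior, 10.0, atol=1e-6)


def test_sinusoid_peak_velocity():
    """Peak velocity of A*sin(2 pi f t) approximates 2 pi f A."""
    f, A = 2.0, 1.5
    t = np.arange(2000) / 1000.0
    kin = estimate_kinematics(_angles_from_deg(A * np.sin(2 * np.pi * f * t)))
    peak = np.max(kin.velocity[50:-50])
    assert peak == pytest.approx(2 * np.pi * f * A, rel=0.02)


def test_short_trace_all_invalid():
    kin = estimate_kinematics(_angles_from_deg(np.zeros(5)))
    assert not kin.valid.any()


# -- detect_blinks -----------------------------------------------------------

def test_fully_valid_trace_has_no_blinks():
    assert detect_blinks(constant_gaze(1.0)) == []


def test_blink_padding_arithmetic():
    """A 120 ms invalid run padded by 50 ms becomes one 220 ms interval."""
    trace = constant_gaze(1.0)
    trace.valid[400:520] = False
    (a, b), = detect_blinks(trace, pad=0.05)
    assert a == pytest.approx(0.35)
    assert b == pytest.approx(0.57)


def test_blinks_merge_when_padding_overlaps():
    trace = constant_gaze(1.0)
    trace.valid[300:360] = False
    trace.valid[420:480] = False  # 60 ms apart, pad 50 ms -> merged
    blinks = detect_blinks(trace, pad=0.05)
    assert len(blinks) == 1
    assert blinks[0][0] == pytest.approx(0.25)
    assert blinks[0][1] == pytest.approx(0.53)


# -- classify_events ---------------------------------------------------------

def _plant_saccades(n_sacc=10, fix_ms=300, sacc_ms=20, peak_deg_s=300.0,
                    screen=ScreenGeometry(), seed=0):
    """Horizontal raised-cosine saccades separated by constant fixations."""
    rng = np.random.default_rng(seed)
    deg_px = degrees_per_pixel(screen)
    amp_px = (peak_deg_s * sacc_ms / 1000.0 / 2.0) / deg_px
    xs, amps = [], []
    x0 = 300.0
    for k in range(n_sacc + 1):
        xs.append(np.full(fix_ms, x0))
        if k < n_sacc:
            sign = 1.0 if (x0 < 700 or rng.random() < 0.3) else -1.0
            if x0 + sign * amp_px > screen.width_px - 50 or \
               x0 + sign * amp_px < 50:
                sign = -sign
            u = np.arange(sacc_ms) / sacc_ms
            prof = u - np.sin(2 * np.pi * u) / (2 * np.pi)
            xs.append(x0 + sign * amp_px * prof)
            amps.append(amp_px)
            x0 = x0 + sign * amp_px
    x = np.concatenate(xs)
    n = x.size
    return GazeTrace(0.0, 1000.0, x, np.full(n, 400.0),
                     np.ones(n, dtype=bool)), np.asarray(amps)


def test_constant_gaze_is_single_fixation(screen):
    events = detect_gaze_events(constant_gaze(4.0), screen)
    assert list(events["kind"]) == ["fixation"]
    assert events.loc[0, "t_end"] - events.loc[0, "t_start"] \
        == pytest.approx(4.0)
    assert events.loc[0, "centroid_x"] == pytest.approx(500.0)


def test_velocity_just_above_threshold_is_saccade():
    """A sustained 31 deg/s motion exceeds the 30 deg/s criterion and is
    saccade-labelled even with negligible acceleration."""
    from drivegaze.events import AngularPosition, KinematicSeries
    n = 200
    kin = KinematicSeries(0.0, 1000.0, np.full(n, 31.0), np.zeros(n),
                          np.ones(n, dtype=bool))
    trace = constant_gaze(n / 1000.0)
    events = classify_events(kin, [], trace)
    assert set(events["kind"]) == {"saccade"}
    kin30 = KinematicSeries(0.0, 1000.0, np.full(n, 30.0), np.zeros(n),
                            np.ones(n, dtype=bool))
    events30 = classify_events(kin30, [], trace)
    assert set(events30["kind"]) == {"fixation"}  # strict inequality


def test_planted_saccade_counts_and_amplitudes(screen):
    """10 planted 300 deg/s saccades with 300 ms fixations: exactly 10
    saccades and 11 fixations; amplitudes within 1 px of planted."""
    trace, amps = _plant_saccades(screen=screen)
    events = detect_gaze_events(trace, screen)
    fix = events[events["kind"] == "fixation"]
    sac = events[events["kind"] == "saccade"]
    assert len(fix) == 11
    assert len(sac) == 10
    assert np.all(np.abs(sac["amplitude_px"].to_numpy() - amps) <= 1.0)


def test_partition_property(screen):
    """Event intervals plus residual invalid time tile the trace."""
    p = GazeParams(missing_fraction=0.1)
    trace, _ = generate_gaze([], tiled_params_windows(10, p), screen, seed=6)
    events = detect_gaze_events(trace, screen)
    ev = events.sort_values("t_start")
    for a, b in zip(ev.itertuples(), list(ev.itertuples())[1:]):
        assert b.t_start >= a.t_end - 1e-9  # non-overlapping
    covered = (ev["t_end"] - ev["t_start"]).sum()
    kin_invalid_margin = 0.1 * 2 * len(ev)  # generous bound on erosion
    assert covered <= trace.duration + 1e-6
    # every valid-and-classified sample lies inside exactly one event
    inside = np.zeros(len(trace), dtype=bool)
    for r in ev.itertuples():
        sl = trace.sample_slice(r.t_start, r.t_end)
        assert not inside[sl].any()
        inside[sl] = True
    # residual uncovered time is invalid or erosion margin near blinks
    uncovered = ~inside
    assert uncovered.mean() < 0.05


def test_raising_velocity_threshold_monotone(screen):
    trace, _ = _plant_saccades(n_sacc=8, peak_deg_s=120.0, screen=screen)
    counts = []
    for vt in (20.0, 30.0, 60.0, 200.0):
        ev = detect_gaze_events(trace, screen, velocity_threshold=vt,
                                accel_threshold=1e12)
        counts.append((ev["kind"] == "saccade").sum())
    assert counts == sorted(counts, reverse=True)


def test_planted_count_recovery_across_seeds(screen):
    """Detected saccade count equals planted count on generator traces whose
    planted amplitudes exceed 1 deg and peak velocities exceed 3x threshold."""
    deg_px = degrees_per_pixel(screen)
    p = GazeParams(saccade_amplitude_mean=250, saccade_amplitude_sd=40,
                   missing_fraction=0.0)
    ok_windows = total_windows = 0
    for seed in range(20):
        trace, gt = generate_gaze([], tiled_params_windows(5, p), screen,
                                  seed=seed)
        amps_deg = gt.saccade_amplitudes_px * deg_px
        peak_v = 2 * amps_deg / (p.saccade_duration / 1000.0)
        if not (np.all(amps_deg > 1.0) and np.all(peak_v > 90.0)):
            continue
        if gt.saccade_onsets.size and \
                gt.saccade_onsets[-1] + 0.03 > trace.duration:
            continue  # last saccade truncated by the trace edge
        events = detect_gaze_events(trace, screen)
        n_detected = (events["kind"] == "saccade").sum()
        total_windows += 1
        if n_detected == gt.saccade_onsets.size:
            ok_windows += 1
    assert total_windows > 0
    assert ok_windows == total_windows


def test_all_invalid_trace_yields_empty_events(screen):
    trace = constant_gaze(0.5)
    trace.valid[:] = False
    trace.x[:] = np.nan
    trace.y[:] = np.nan
    events = detect_gaze_events(trace, screen)
    assert set(events["kind"]) <= {"blink"}
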