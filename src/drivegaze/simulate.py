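"""Synthetic driving-session generator with known ground truth.

Emulates the three repeated-trial scenarios of the event-based simulated
driving paradigm — an unanticipated-steering (wind gust) task, a traffic-light
braking task, and a lead-car braking task — each trial followed by a 9 s rest.
Four generators produce, deterministically from a seed:

* trial schedules (``generate_task_schedule``),
* pedal/steering telemetry with flat coasting plateaus and event-locked
  responses (``generate_telemetry``),
* a 1000 Hz gaze trace as an alternating fixation/saccade renewal process
  with blink gaps (``generate_gaze``), and
* a 600 Hz neural trace whose 3–9 Hz component is boosted inside
  high-cognitive-control windows (``generate_neural``).

Gaze model
----------
Fixation durations follow a log-normal law (moment-matched to the configured
mean/SD, truncated below at 50 ms).  Fixation centres follow a first-order
autoregressive process whose stationary marginal is exactly the configured
bivariate normal N(center, spread); the AR persistence is derived from the
configured saccade-amplitude root-mean-square, so consecutive-centre distances
reproduce the configured amplitude scale.  Saccades move between centres with
a raised-cosine velocity profile of configurable duration, which guarantees a
well-defined peak velocity against the 30 deg/s detector criterion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ScheduleError
from .events import degrees_per_pixel
from .theta import bandpass_fft
from .traces import GazeTrace, NeuralTrace, ScreenGeometry, TelemetryTrace


class TaskKind(str, enum.Enum):
    """The three prototypical driving scenarios."""

    UNANTICIPATED_STEERING = "unanticipated_steering"
    TRAFFIC_LIGHT_BRAKING = "traffic_light_braking"
    LEAD_CAR_BRAKING = "lead_car_braking"

    @classmethod
    def parse(cls, name: str) -> "TaskKind":
        aliases = {"steer": cls.UNANTICIPATED_STEERING,
                   "light": cls.TRAFFIC_LIGHT_BRAKING,
                   "lead": cls.LEAD_CAR_BRAKING}
        if name in aliases:
            return aliases[name]
        return cls(name)


#: Default trial counts: 20 trials for the steering and traffic-light tasks,
#: 14 lead-vehicle braking events.
DEFAULT_TRIALS = {
    TaskKind.UNANTICIPATED_STEERING: 20,
    TaskKind.TRAFFIC_LIGHT_BRAKING: 20,
    TaskKind.LEAD_CAR_BRAKING: 14,
}

REST_DURATION = 9.0


@dataclass(frozen=True)
class TrialSchedule:
    """One trial: driving phase, embedded event, and the following rest."""

    task: TaskKind
    trial_id: int
    t_start: float
    t_event: float
    t_rest_start: float
    t_rest_end: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_event < self.t_rest_start
                < self.t_rest_end):
            raise ScheduleError("trial times must be strictly increasing")
        if abs((self.t_rest_end - self.t_rest_start) - REST_DURATION) > 1e-9:
            raise ScheduleError("rest period must last 9 s")


@dataclass(frozen=True)
class ScheduleTiming:
    """Session layout knobs (seconds).  The event time is jittered uniformly
    within [plateau_min, plateau_max] after the acceleration phase."""

    t0: float = 0.0
    accel_duration: float = 3.0
    plateau_min: float = 6.0
    plateau_max: float = 10.0
    response_duration: float = 5.0
    rest_duration: float = REST_DURATION


def generate_task_schedule(task: TaskKind, n_trials: int | None = None,
                           seed: int = 0,
                           timing: ScheduleTiming = ScheduleTiming()
                           ) -> list[TrialSchedule]:
    """Non-overlapping, strictly increasing trial schedules.

    ``n_trials=None`` uses the task default (20/20/14)."""
    task = TaskKind.parse(task) if not isinstance(task, TaskKind) else task
    if n_trials is None:
        n_trials = DEFAULT_TRIALS[task]
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)
    trials = []
    t = timing.t0
    for i in range(n_trials):
        plateau = rng.uniform(timing.plateau_min, timing.plateau_max)
        t_event = t + timing.accel_duration + plateau
        t_rest_start = t_event + timing.response_duration
        t_rest_end = t_rest_start + timing.rest_duration
        trials.append(TrialSchedule(task, i + 1, t, t_event,
                                    t_rest_start, t_rest_end))
        t = t_rest_end
    return trials


def session_duration(schedule: list[TrialSchedule]) -> float:
    return schedule[-1].t_rest_end - schedule[0].t_start if schedule else 0.0


# ---------------------------------------------------------------------------
# telemetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelemetryParams:
    """Telemetry synthesis parameters (normalized control units)."""

    sample_rate: float = 60.0
    gas_plateau: float = 0.35
    plateau_noise_sd: float = 0.01
    steering_noise_sd: float = 0.005
    brake_level: float = 0.8
    brake_ramp: float = 0.25
    steer_level: float = 0.3
    steer_ramp: float = 0.3
    steer_return: float = 1.5
    reaction_delay: float = 0.0
    lead_curve_amplitude: float = 0.15
    lead_curve_period: float = 30.0
    speed_cruise: float = 1.0


def generate_telemetry(schedule: list[TrialSchedule],
                       params: TelemetryParams = TelemetryParams(),
                       seed: int = 0) -> TelemetryTrace:
    """Per-trial telemetry: acceleration ramp, low-variance plateau, and an
    event-locked brake ramp (braking tasks) or steering deflection with
    corrective return (steering task).  Rests have all controls at zero."""
    if not schedule:
        raise ScheduleError("schedule must be non-empty")
    starts = [tr.t_start for tr in schedule]
    ends = [tr.t_rest_end for tr in schedule]
    for a, b in zip(ends[:-1], starts[1:]):
        if b < a - 1e-9:
            raise ScheduleError("trials overlap")

    fs = params.sample_rate
    t0 = schedule[0].t_start
    n = int(round((schedule[-1].t_rest_end - t0) * fs))
    t = t0 + np.arange(n) / fs
    gas = np.zeros(n)
    brake = np.zeros(n)
    steering = np.zeros(n)
    speed = np.zeros(n)
    rng = np.random.default_rng(seed)

    for tr in schedule:
        task = tr.task
        t_on = tr.t_event + params.reaction_delay
        drive = (t >= tr.t_start) & (t < tr.t_rest_start)
        accel_end = min(tr.t_start + 3.0, tr.t_event)
        accel = (t >= tr.t_start) & (t < accel_end)
        plateau = (t >= accel_end) & (t < min(t_on, tr.t_rest_start))

        if task is TaskKind.LEAD_CAR_BRAKING:
            # throttle and steering are simulation-controlled while following
            gas[drive] = 0.3
            phase = 2 * np.pi * (t[drive] - tr.t_start) / params.lead_curve_period
            steering[drive] = (params.lead_curve_amplitude * np.sin(phase)
                               + rng.normal(0.0, params.steering_noise_sd,
                                            drive.sum()))
        else:
            gas[accel] = (params.gas_plateau
                          * (t[accel] - tr.t_start) / (accel_end - tr.t_start))
            gas[plateau] = params.gas_plateau + rng.normal(
                0.0, params.plateau_noise_sd, plateau.sum())
            steering[drive] += rng.normal(0.0, params.steering_noise_sd,
                                          drive.sum())

        resp = (t >= t_on) & (t < tr.t_rest_start)
        if task is TaskKind.UNANTICIPATED_STEERING:
            # gust response: deflection then corrective return; gas held
            gas[resp] = params.gas_plateau + rng.normal(
                0.0, params.plateau_noise_sd, resp.sum())
            sign = 1.0 if rng.random() < 0.5 else -1.0
            u = t[resp] - t_on + 1.0 / fs
            deflect = np.clip(u / params.steer_ramp, 0.0, 1.0)
            ret = np.clip((u - params.steer_ramp) / params.steer_return,
                          0.0, 1.0)
            steering[resp] += sign * params.steer_level * deflect * (1.0 - ret)
        else:
            gas[resp] = 0.0
            u = t[resp] - t_on + 1.0 / fs
            brake[resp] = params.brake_level * np.clip(
                u / params.brake_ramp, 0.0, 1.0)

        # piecewise-trapezoid speed profile (arbitrary units)
        drv = drive
        v = np.zeros(drv.sum())
        td = t[drv]
        ramp_up = np.clip((td - tr.t_start) / max(accel_end - tr.t_start, 1e-9),
                          0.0, 1.0)
        if task is TaskKind.UNANTICIPATED_STEERING:
            v = params.speed_cruise * ramp_up
        else:
            stop_t = t_on + 2.0
            ramp_down = np.clip((td - t_on) / max(stop_t - t_on, 1e-9), 0.0, 1.0)
            v = params.speed_cruise * ramp_up * (1.0 - ramp_down)
        speed[drv] = v

    np.clip(gas, 0.0, 1.0, out=gas)
    np.clip(brake, 0.0, 1.0, out=brake)
    np.clip(steering, -1.0, 1.0, out=steering)
    return TelemetryTrace(t0, fs, gas, brake, steering, speed)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeParams:
    """Generative parameters of the alternating fixation/saccade process.

    Defaults reproduce typical coasting-period scanning on a 1024x768 screen:
    ~314 ms fixations centred low-right of screen centre with ~170 px spread.
    ``missing_fraction`` is the expected proportion of blink/missing samples.
    """

    fixation_duration_mean: float = 314.0   # ms
    fixation_duration_sd: float = 100.0     # ms
    gaze_center_x: float = 843.0            # px
    gaze_center_y: float = 789.0            # px
    gaze_spread_x: float = 165.0            # px (SD of fixation centres)
    gaze_spread_y: float = 176.0            # px
    saccade_amplitude_mean: float = 169.0   # px
    saccade_amplitude_sd: float = 39.0      # px
    saccade_duration: float = 20.0          # ms
    jitter_px: float = 2.0                  # within-fixation SD, << spread
    missing_fraction: float = 0.05
    blink_duration_mean: float = 150.0      # ms
    blink_duration_sd: float = 50.0         # ms
    min_fixation_duration: float = 50.0     # ms, truncation bound

    def __post_init__(self) -> None:
        if self.fixation_duration_mean <= 0 or self.saccade_duration <= 0:
            raise ValueError("durations must be positive")
        if self.gaze_spread_x < 0 or self.gaze_spread_y < 0:
            raise ValueError("spreads must be non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted generative record for one gaze trace."""

    seed: int
    window_params: list[tuple[tuple[float, float], GazeParams]]
    fixation_onsets: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    fixation_durations: np.ndarray = field(
        default_factory=lambda: np.empty(0))  # seconds
    fixation_centers: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2)))
    saccade_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    saccade_amplitudes_px: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _draw_truncated_lognormal(rng, mean, sd, lower, size=1):
    mu, sigma = _lognormal_moments(mean, sd)
    out = rng.lognormal(mu, sigma, size)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            break
        out[bad] = rng.lognormal(mu, sigma, bad.sum())
    return np.maximum(out, lower)


#: smallest plantable saccade (deg): the practical amplitude resolution of
#: the 30 deg/s velocity criterion at 1000 Hz with default smoothing
_MIN_SACCADE_AMP_DEG = 0.55


def ar_persistence(params: GazeParams) -> float:
    """AR(1) coefficient reproducing the configured saccade-amplitude RMS.

    For a stationary AR(1) centre process with marginal N(center, spread),
    E|step|^2 = 2 (1 - rho) (sx^2 + sy^2); solving for rho matches the
    configured amplitude root-mean-square.  Clamped to [-1, 1]."""
    s2 = params.gaze_spread_x ** 2 + params.gaze_spread_y ** 2
    if s2 == 0:
        return 1.0
    amp2 = params.saccade_amplitude_mean ** 2 + params.saccade_amplitude_sd ** 2
    return float(np.clip(1.0 - amp2 / (2.0 * s2), -1.0, 1.0))


def generate_gaze(schedule: list[TrialSchedule],
                  windows: list[tuple[tuple[float, float], GazeParams]],
                  screen: ScreenGeometry = ScreenGeometry(),
                  seed: int = 0,
                  default_params: GazeParams | None = None,
                  sample_rate: float = 1000.0,
                  velocity_criterion: float = 30.0,
                  ) -> tuple[GazeTrace, GroundTruth]:
    """Simulate a 1000 Hz gaze trace over the session.

    ``windows`` maps half-open time intervals to generative parameters; a
    fixation draws its parameters from the interval containing its onset
    (``default_params``, or the first window's parameters, elsewhere).
    Saccades whose planted peak velocity falls below ``velocity_criterion``
    under ``screen`` are recorded as warnings in the ground truth.
    """
    windows = sorted(windows, key=lambda w: w[0][0])
    for (a0, b0), (a1, _b1) in zip([w[0] for w in windows],
                                   [w[0] for w in windows[1:]]):
        if a1 < b0 - 1e-9:
            raise ValueError("gaze parameter windows overlap")
    duration = max([session_duration(schedule)]
                   + [w[0][1] for w in windows] + [0.0])
    n = int(round(duration * sample_rate))
    gt = GroundTruth(seed=seed, window_params=list(windows))
    if n == 0:
        trace = GazeTrace(0.0, sample_rate, np.empty(0), np.empty(0),
                          np.empty(0, dtype=bool))
        return trace, gt

    if default_params is None:
        default_params = windows[0][1] if windows else GazeParams()

    bounds = np.array([w[0][0] for w in windows])

    def params_at(time: float) -> GazeParams:
        if windows:
            k = int(np.searchsorted(bounds, time, side="right")) - 1
            if k >= 0 and time < windows[k][0][1]:
                return windows[k][1]
        return default_params

    rng = np.random.default_rng(seed)
    deg_px = degrees_per_pixel(screen)
    x = np.empty(n)
    y = np.empty(n)
    fix_on, fix_dur, fix_cen = [], [], []
    sac_on, sac_amp = [], []

    p0 = params_at(0.0)
    pos = np.array([p0.gaze_center_x + p0.gaze_spread_x * rng.standard_normal(),
                    p0.gaze_center_y + p0.gaze_spread_y * rng.standard_normal()])
    t_cur = 0.0
    small_amp_warned = False
    while t_cur < duration:
        p = params_at(t_cur)
        dur_s = float(_draw_truncated_lognormal(
            rng, p.fixation_duration_mean, p.fixation_duration_sd,
            p.min_fixation_duration)[0]) / 1000.0
        i0 = int(round(t_cur * sample_rate))
        i1 = min(n, int(round((t_cur + dur_s) * sample_rate)))
        m = i1 - i0
        if m > 0:
            x[i0:i1] = pos[0] + rng.normal(0.0, p.jitter_px, m)
            y[i0:i1] = pos[1] + rng.normal(0.0, p.jitter_px, m)
        fix_on.append(t_cur)
        fix_dur.append(dur_s)
        fix_cen.append(pos.copy())
        t_cur += dur_s
        if t_cur >= duration:
            break
        # saccade to the next AR(1) centre; draws whose step falls below the
        # detector's practical amplitude resolution are redrawn
        rho = ar_persistence(p)
        center = np.array([p.gaze_center_x, p.gaze_center_y])
        spread = np.array([p.gaze_spread_x, p.gaze_spread_y])
        min_amp_px = _MIN_SACCADE_AMP_DEG / deg_px
        sq = math.sqrt(max(0.0, 1.0 - rho * rho))
        nxt = pos
        amp = 0.0
        for _ in range(100):
            nxt = (center + rho * (pos - center)
                   + sq * spread * rng.standard_normal(2))
            amp = float(np.hypot(*(nxt - pos)))
            if amp >= min_amp_px or sq * max(spread) < min_amp_px:
                break
        T = p.saccade_duration / 1000.0
        peak_vel = 2.0 * amp * deg_px / T
        if peak_vel <= velocity_criterion and not small_amp_warned:
            gt.warnings.append(
                f"saccade at t={t_cur:.3f}s: peak velocity "
                f"{peak_vel:.1f} deg/s <= detector criterion "
                f"{velocity_criterion} deg/s")
            small_amp_warned = True
        j0 = int(round(t_cur * sample_rate))
        j1 = min(n, int(round((t_cur + T) * sample_rate)))
        if j1 > j0:
            u = (np.arange(j0, j1) / sample_rate - t_cur) / T
            s = u - np.sin(2 * np.pi * u) / (2 * np.pi)  # raised-cosine vel
            x[j0:j1] = pos[0] + (nxt[0] - pos[0]) * s
            y[j0:j1] = pos[1] + (nxt[1] - pos[1]) * s
        sac_on.append(t_cur)
        sac_amp.append(amp)
        t_cur += T
        pos = nxt

    np.clip(x, 0.0, screen.width_px - 1.0, out=x)
    np.clip(y, 0.0, screen.height_px - 1.0, out=y)

    # blink gaps: Poisson-placed invalid runs; the rate is chosen so the
    # expected coverage equals missing_fraction (overlap-corrected)
    valid = np.ones(n, dtype=bool)
    segs = _params_timeline(windows, default_params, duration)
    for (a, b), p in segs:
        if p.missing_fraction <= 0.0:
            continue
        lam = -math.log(1.0 - p.missing_fraction) \
            / (p.blink_duration_mean / 1000.0)
        k = rng.poisson(lam * (b - a))
        if k == 0:
            continue
        onsets = np.sort(rng.uniform(a, b, k))
        durs = _draw_truncated_lognormal(
            rng, p.blink_duration_mean, p.blink_duration_sd, 10.0, k) / 1000.0
        for o, d in zip(onsets, durs):
            i0 = max(0, int(round(o * sample_rate)))
            i1 = min(n, int(round((o + d) * sample_rate)))
            if i1 > i0:
                valid[i0:i1] = False
                gt.blink_intervals.append((i0 / sample_rate, i1 / sample_rate))
    x[~valid] = np.nan
    y[~valid] = np.nan

    gt.fixation_onsets = np.asarray(fix_on)
    gt.fixation_durations = np.asarray(fix_dur)
    gt.fixation_centers = (np.asarray(fix_cen).reshape(-1, 2)
                           if fix_cen else np.empty((0, 2)))
    gt.saccade_onsets = np.asarray(sac_on)
    gt.saccade_amplitudes_px = np.asarray(sac_amp)
    trace = GazeTrace(0.0, sample_rate, x, y, valid)
    return trace, gt


def _params_timeline(windows, default_params, duration):
    """Partition [0, duration) into (interval, params) segments."""
    segs = []
    t = 0.0
    for (a, b), p in windows:
        a, b = max(0.0, a), min(duration, b)
        if a > t:
            segs.append(((t, a), default_params))
        if b > a:
            segs.append(((a, b), p))
        t = max(t, b)
    if t < duration:
        segs.append(((t, duration), default_params))
    return segs


# ---------------------------------------------------------------------------
# neural
# ---------------------------------------------------------------------------

def generate_neural(schedule: list[TrialSchedule],
                    hi_windows: list[tuple[float, float]],
                    theta_boost: float = 1.0,
                    seed: int = 0,
                    sample_rate: float = 600.0,
                    band: tuple[float, float] = (3.0, 9.0),
                    background_rms: float = 1.0,
                    theta_rms: float = 1.0,
                    taper: float = 0.25,
                    duration: float | None = None) -> NeuralTrace:
    """1/f-shaped background plus a band-limited 3–9 Hz oscillation whose
    amplitude is multiplied by ``theta_boost`` inside ``hi_windows`` (cosine
    tapers of ``taper`` seconds at the window edges)."""
    if theta_boost < 1.0:
        raise ValueError("theta_boost must be >= 1")
    if duration is None:
        duration = max([session_duration(schedule)]
                       + [b for _, b in hi_windows] + [0.0])
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)

    background = np.zeros(n)
    if background_rms > 0.0 and n > 1:
        from scipy import fft as sp_fft
        nfft = sp_fft.next_fast_len(n)
        white = rng.standard_normal(nfft)
        spec = sp_fft.rfft(white)
        f = sp_fft.rfftfreq(nfft, d=1.0 / sample_rate)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** -0.5  # 1/f power spectrum
        background = sp_fft.irfft(spec * shape, nfft)[:n]
        background *= background_rms / max(background.std(), 1e-30)

    theta = np.zeros(n)
    if theta_rms > 0.0 and n > 1:
        theta = bandpass_fft(rng.standard_normal(n), sample_rate, band)
        theta *= theta_rms / max(theta.std(), 1e-30)

    envelope = np.ones(n)
    t = np.arange(n) / sample_rate
    for a, b in hi_windows:
        inside = np.clip(np.minimum(t - a, b - t) / max(taper, 1e-9), 0.0, 1.0)
        inside[(t < a) | (t >= b)] = 0.0
        ramp = 0.5 - 0.5 * np.cos(np.pi * inside)  # 0 -> 1 cosine taper
        envelope = np.maximum(envelope, 1.0 + (theta_boost - 1.0) * ramp)

    return NeuralTrace(sample_rate, background + theta * envelope)
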