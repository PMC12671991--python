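"""Run configuration: one JSON-serializable object controlling every stage.

``TASK_GAZE_PARAMS`` holds the condition-dependent generative gaze parameters
per task (low- vs high-cognitive-control scanning regimes); they are the
study conditions the synthetic sessions emulate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

from .segmentation import TaskRules
from .simulate import (DEFAULT_TRIALS, GazeParams, ScheduleTiming, TaskKind,
                       TelemetryParams)
from .traces import ScreenGeometry


def _gp(fix_mean, fix_sd, cx, cy, sx, sy, amp_mean, amp_sd) -> GazeParams:
    return GazeParams(
        fixation_duration_mean=fix_mean, fixation_duration_sd=fix_sd,
        gaze_center_x=cx, gaze_center_y=cy,
        gaze_spread_x=sx, gaze_spread_y=sy,
        saccade_amplitude_mean=amp_mean, saccade_amplitude_sd=amp_sd)


#: Condition-dependent gaze regimes per task: Lo = coasting/following,
#: Hi = braking/steering.  Rest periods reuse the Lo regime.
TASK_GAZE_PARAMS: dict[TaskKind, dict[str, GazeParams]] = {
    TaskKind.UNANTICIPATED_STEERING: {
        "Lo": _gp(314, 100, 843, 789, 165, 176, 169, 39),
        "Hi": _gp(425, 200, 926, 697, 107, 111, 111, 37),
    },
    TaskKind.TRAFFIC_LIGHT_BRAKING: {
        "Lo": _gp(339, 125, 839, 738, 160, 174, 176, 34),
        "Hi": _gp(429, 146, 932, 652, 147, 147, 162, 64),
    },
    TaskKind.LEAD_CAR_BRAKING: {
        "Lo": _gp(379, 105, 943, 589, 83, 50, 92, 38),
        "Hi": _gp(441, 162, 927, 582, 73, 52, 81, 45),
    },
}


@dataclass(frozen=True)
class DetectorConfig:
    """Gaze event-detector knobs."""

    velocity_threshold: float = 30.0     # deg/s
    accel_threshold: float = 8000.0      # deg/s^2
    min_saccade: float = 0.008           # s
    min_fixation: float = 0.050          # s
    blink_pad: float = 0.05              # s


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, serializable to one JSON file."""

    tasks: list[str] = field(default_factory=lambda: [t.value for t in TaskKind])
    trials_per_task: dict[str, int] = field(
        default_factory=lambda: {t.value: n for t, n in DEFAULT_TRIALS.items()})
    n_participants: int = 7
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    timing: ScheduleTiming = field(default_factory=ScheduleTiming)
    telemetry: TelemetryParams = field(default_factory=TelemetryParams)
    rules: TaskRules = field(default_factory=TaskRules)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    max_missing: float = 0.20
    missing_fraction: float | None = None  # overrides the per-task gaze value
    theta_boost: float = 2.0
    theta_band: tuple[float, float] = (3.0, 9.0)
    theta_threshold: float = 2.0
    include_neural: bool = True

    def task_kinds(self) -> list[TaskKind]:
        return [TaskKind.parse(t) for t in self.tasks]

    def gaze_params_for(self, task: TaskKind) -> dict[str, GazeParams]:
        return TASK_GAZE_PARAMS[task]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_band"] = list(self.theta_band)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, typ in (("screen", ScreenGeometry), ("timing", ScheduleTiming),
                         ("telemetry", TelemetryParams), ("rules", TaskRules),
                         ("detector", DetectorConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if "theta_band" in kwargs:
            kwargs["theta_band"] = tuple(kwargs["theta_band"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))
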