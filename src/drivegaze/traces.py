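"""Core in-memory containers: screen geometry and uniformly sampled traces.

All timestamps are seconds from session start; intervals are half-open
``[t_start, t_end)``.  Gaze positions are screen pixels with the origin at the
upper-left corner (x rightward, y downward), the native output convention of
video eye trackers.  Invalid gaze samples carry NaN coordinates and a False
validity flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry needed to convert pixels to visual angle.

    Defaults describe a 1600x1200 px back-projected panel with a 34 x 25.5 cm
    active area viewed from 90 cm, typical of projection setups used inside
    magnetically shielded rooms.
    """

    width_px: int = 1600
    height_px: int = 1200
    width_cm: float = 34.0
    height_cm: float = 25.5
    viewing_distance_cm: float = 90.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")
        px, py = self.pitch_x_cm, self.pitch_y_cm
        if abs(px - py) > 0.05 * max(px, py):
            raise ValueError(
                "anisotropic pixel pitch: width_cm/width_px and "
                "height_cm/height_px differ by more than 5%"
            )

    @property
    def pitch_x_cm(self) -> float:
        return self.width_cm / self.width_px

    @property
    def pitch_y_cm(self) -> float:
        return self.height_cm / self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


def _as_array(x, dtype=float) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=dtype))


@dataclass
class GazeTrace:
    """Uniformly sampled on-screen gaze with per-sample validity."""

    t0: float
    sample_rate: float
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.x = _as_array(self.x)
        self.y = _as_array(self.y)
        self.valid = _as_array(self.valid, dtype=bool)
        if not (self.x.shape == self.y.shape == self.valid.shape):
            raise ValueError("x, y and valid must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.x.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.x.size / self.sample_rate

    def sample_slice(self, t_start: float, t_end: float) -> slice:
        """Sample indices covering the half-open interval [t_start, t_end)."""
        i0 = int(round((t_start - self.t0) * self.sample_rate))
        i1 = int(round((t_end - self.t0) * self.sample_rate))
        return slice(i0, i1)


@dataclass
class TelemetryTrace:
    """Simulator control/vehicle channels (gas, brake, steering, speed)."""

    t0: float
    sample_rate: float
    gas: np.ndarray
    brake: np.ndarray
    steering: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.gas = _as_array(self.gas)
        self.brake = _as_array(self.brake)
        self.steering = _as_array(self.steering)
        self.speed = _as_array(self.speed)
        n = self.gas.size
        if not all(a.size == n for a in (self.brake, self.steering, self.speed)):
            raise ValueError("telemetry channels must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.gas.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.gas.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.gas.size / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in ("gas", "brake", "steering", "speed"):
            raise ValueError(f"unknown telemetry channel {name!r}")
        return getattr(self, name)

    def sample_slice(self, t_start: float, t_end: float) -> slice:
        i0 = int(round((t_start - self.t0) * self.sample_rate))
        i1 = int(round((t_end - self.t0) * self.sample_rate))
        return slice(i0, i1)


@dataclass
class NeuralTrace:
    """Single-channel neural time series (default 600 Hz)."""

    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = _as_array(self.samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("neural samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def sample_slice(self, t_start: float, t_end: float) -> slice:
        i0 = int(round((t_start - self.t0) * self.sample_rate))
        i1 = int(round((t_end - self.t0) * self.sample_rate))
        return slice(i0, i1)
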