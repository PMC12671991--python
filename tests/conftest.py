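import numpy as np
import pandas as pd
import pytest

from drivegaze import GazeParams, GazeTrace, ScreenGeometry

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is optional
    pass


@pytest.fixture(scope="session")
def screen() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def constant_gaze(duration: float = 4.0, x: float = 500.0, y: float = 400.0,
                  fs: float = 1000.0) -> GazeTrace:
    n = int(round(duration * fs))
    return GazeTrace(0.0, fs, np.full(n, x), np.full(n, y),
                     np.ones(n, dtype=bool))


def windows_frame(n: int, length: float = 4.0, label: str = "Lo"
                  ) -> pd.DataFrame:
    return pd.DataFrame(
        [{"trial_id": i, "label": label, "t_start": length * i,
          "t_end": length * (i + 1)} for i in range(n)])


def tiled_params_windows(n: int, params: GazeParams, length: float = 4.0):
    return [((length * i, length * (i + 1)), params) for i in range(n)]
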