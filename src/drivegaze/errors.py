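"""Exception hierarchy for drivegaze."""


class DriveGazeError(Exception):
    """Base class for all drivegaze errors."""


class ScheduleError(DriveGazeError):
    """Trial schedule is inconsistent (overlaps, bad ordering)."""


class FormatError(DriveGazeError):
    """An input file could not be parsed or violates its contract."""


class DegenerateVarianceError(DriveGazeError):
    """A statistic is undefined because the relevant variance is zero."""


class InsufficientDataError(DriveGazeError):
    """Too few usable trials/windows to compute the requested quantity."""
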