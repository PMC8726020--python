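"""Domain types shared across the pipeline.

The pipeline works on single-task lumbar IMU recordings: a subject performs
one known balance task (sit-to-stand, a 360-degree turn, or stand-to-sit)
bracketed by non-task idling.  All times are 0-based seconds from the start
of the recording; motion intervals are closed ``[start_s, end_s]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Task",
    "Condition",
    "IntervalSource",
    "FULL_MARKS",
    "ValidationError",
    "FormatError",
    "ImuRecording",
    "MotionInterval",
    "GroundTruthLabel",
]


class ValidationError(ValueError):
    """Raised when a value violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class Task(str, enum.Enum):
    SIT_TO_STAND = "sit_to_stand"
    TURN_360 = "turn_360"
    STAND_TO_SIT = "stand_to_sit"


class Condition(str, enum.Enum):
    NORMAL = "normal"
    DEVIATING = "deviating"


class IntervalSource(str, enum.Enum):
    GROUND_TRUTH = "ground_truth"
    MANUAL = "manual"
    DETECTED = "detected"


#: Full Tinetti POMA-B marks per task; a subject scoring below the full mark
#: on a task is labelled "deviating from healthy" for that task.
FULL_MARKS: dict[Task, int] = {
    Task.SIT_TO_STAND: 4,
    Task.TURN_360: 2,
    Task.STAND_TO_SIT: 2,
}

#: Semantic axis order used throughout: anterior-posterior, medio-lateral,
#: vertical.  The vertical axis is the yaw (turning) axis.
AXES = ("ap", "ml", "v")


@dataclass
class ImuRecording:
    """One subject's 6-channel inertial time series for one known task.

    ``accel`` is 3 x T in m/s^2 and ``gyro`` 3 x T in deg/s, rows ordered
    AP, ML, vertical.
    """

    subject_id: str
    task: Task
    time_s: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sampling_rate_hz: float = 40.0
    axis_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        t = self.time_s.size
        if t == 0:
            raise ValidationError("recording is empty")
        if self.accel.shape != (3, t) or self.gyro.shape != (3, t):
            raise ValidationError(
                f"channel shapes {self.accel.shape}/{self.gyro.shape} "
                f"inconsistent with T={t}"
            )
        if t > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValidationError("time_s must be strictly increasing")
            nominal = 1.0 / self.sampling_rate_hz
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise ValidationError(
                    "time step deviates from 1/sampling_rate_hz by more than 1%"
                )

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class MotionInterval:
    """A detected or annotated closed time interval ``[start_s, end_s]``."""

    start_s: float
    end_s: float
    source: IntervalSource = IntervalSource.GROUND_TRUTH
    degenerate_flag: bool = False

    def __post_init__(self) -> None:
        self.source = IntervalSource(self.source)
        self.start_s = float(self.start_s)
        self.end_s = float(self.end_s)
        if not 0.0 <= self.start_s < self.end_s:
            raise ValidationError(
                f"invalid interval [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "MotionInterval") -> float:
        return max(
            0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s)
        )


@dataclass
class GroundTruthLabel:
    """Observer annotation: the task interval plus the Tinetti POMA-B outcome.

    ``condition`` is derived from the sub-score: a subject is ``normal`` iff
    the sub-score equals the full mark for the task (4 for sit-to-stand,
    2 for turning and stand-to-sit).
    """

    interval: MotionInterval
    task: Task
    tinetti_subscore: int
    #: For synthetic labels only: the drawn generating feature value
    #: (attempt count or average turning speed); None for real annotations.
    generating_value: float | None = None
    condition: Condition = field(init=False)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.tinetti_subscore = int(self.tinetti_subscore)
        if self.tinetti_subscore < 0:
            raise ValidationError("tinetti_subscore must be >= 0")
        full = FULL_MARKS[self.task]
        if self.tinetti_subscore > full:
            raise ValidationError(
                f"tinetti_subscore {self.tinetti_subscore} exceeds the "
                f"full mark {full} for {self.task.value}"
            )
        self.condition = (
            Condition.NORMAL
            if self.tinetti_subscore == full
            else Condition.DEVIATING
        )
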