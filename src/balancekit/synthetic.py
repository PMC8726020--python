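"""Seeded generator of synthetic balance-task recordings and feature cohorts.

The study cohort this package targets (59 community-dwelling older adults,
lumbar IMU at 40 Hz) is not publicly deposited, so the generator emulates
its structure: each recording is pre-task idling, one known task motion,
then post-task idling, plus sensor noise.  Templates are parametric, not
resampled human data:

* sit-to-stand / stand-to-sit: ``k`` biphasic anterior-posterior
  acceleration pulses (sine lobes, amplitude 1.5-2.5 m/s^2), where ``k``
  is the number of attempts.  Healthy subjects almost always take one
  attempt; deviating subjects often need several, which is exactly what
  the AP peak-count feature measures.
* turning 360 deg: trapezoidal yaw angular velocity whose cumulative
  displacement reaches 360 deg; the drawn value is the *average* turning
  speed (deg/s), so feature distributions can be calibrated directly to
  the cohort statistics (healthy ~58 deg/s, deviating ~23 deg/s).

Idle segments carry low-frequency postural sway; white Gaussian noise is
added to all channels.  Gyroscope drift is not simulated (the sensor
class drifts at ~0.05 deg/s and tasks last well under 30 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    Condition,
    FULL_MARKS,
    GroundTruthLabel,
    ImuRecording,
    IntervalSource,
    MotionInterval,
    Task,
    ValidationError,
)

__all__ = ["SynthParams", "synth_recording", "synth_cohort", "synth_features"]

FS_HZ = 40.0

#: Attempt-count tables per task and condition, calibrated so that the
#: implied peak-count means sit near the cohort statistics (healthy
#: ~1.0 peaks; deviating ~2.4 for sit-to-stand, ~1.5-1.8 for
#: stand-to-sit).
ATTEMPT_TABLES: dict[Task, dict[Condition, dict[int, float]]] = {
    Task.SIT_TO_STAND: {
        Condition.NORMAL: {1: 0.95, 2: 0.05},
        Condition.DEVIATING: {1: 0.20, 2: 0.40, 3: 0.25, 4: 0.15},
    },
    Task.STAND_TO_SIT: {
        Condition.NORMAL: {1: 0.97, 2: 0.03},
        Condition.DEVIATING: {1: 0.35, 2: 0.50, 3: 0.15},
    },
}

#: Average-turning-speed distributions (mean, sd, lower, upper) in deg/s;
#: draws are normal clipped to [lower, upper].
TURN_SPEED_DISTS: dict[Condition, tuple[float, float, float, float]] = {
    Condition.NORMAL: (58.16, 19.22, 20.0, 100.0),
    Condition.DEVIATING: (23.46, 13.96, 8.0, 60.0),
}


def _check_table(table: dict[int, float]) -> None:
    if not table:
        raise ValidationError("attempts table is empty")
    probs = np.array(list(table.values()), dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValidationError("attempts table needs non-negative mass summing > 0")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("attempts table must sum to 1")
    if any(int(k) < 1 for k in table):
        raise ValidationError("attempt counts must be >= 1")


@dataclass
class SynthParams:
    """Generator settings; the defaults are the reference study conditions."""

    pre_idle_s: tuple[float, float] = (2.0, 6.0)
    post_idle_s: tuple[float, float] = (1.0, 3.0)
    task_duration_s: tuple[float, float] = (1.5, 3.5)
    ap_pulse_amp: tuple[float, float] = (1.5, 2.5)
    attempts: dict[Task, dict[Condition, dict[int, float]]] = field(
        default_factory=lambda: {
            t: {c: dict(tab) for c, tab in d.items()}
            for t, d in ATTEMPT_TABLES.items()
        }
    )
    turn_speed: dict[Condition, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TURN_SPEED_DISTS)
    )
    turn_ramp_s: float = 0.5
    noise_sd_accel: float = 0.05
    noise_sd_gyro: float = 1.0
    idle_sway_amp: float = 0.1
    pause_prob: float = 0.0  # mid-turn pauses for deviating turns; off by default
    pause_duration_s: tuple[float, float] = (0.3, 1.0)
    sampling_rate_hz: float = FS_HZ

    def __post_init__(self) -> None:
        for name in ("pre_idle_s", "post_idle_s", "task_duration_s",
                     "ap_pulse_amp", "pause_duration_s"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name} must be a positive range")
        for task_tables in self.attempts.values():
            for table in task_tables.values():
                _check_table(table)
        for mean, sd, lo, hi in self.turn_speed.values():
            if sd <= 0 or hi <= lo or lo <= 0:
                raise ValidationError("turn_speed spec must have sd>0, 0<lo<hi")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValidationError("pause_prob must lie in [0, 1]")


def _draw_categorical(rng: np.random.Generator, table: dict[int, float]) -> int:
    keys = np.array(sorted(table), dtype=int)
    probs = np.array([table[int(k)] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _draw_clipped_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
    size: int | None = None,
):
    """Normal draw clipped to [lo, hi]; nearly mean-faithful at ~2-sigma
    bounds (unlike truncation, which shifts the mean by ~0.4 deg/s here)."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _sway(rng: np.random.Generator, t: np.ndarray, amp: float) -> np.ndarray:
    freq = rng.uniform(0.2, 0.5)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return amp * np.sin(2.0 * np.pi * freq * t + phase)


def synth_recording(
    task: Task | str,
    condition: Condition | str,
    params: SynthParams | None = None,
    seed: int = 0,
    subject_id: str | None = None,
    noiseless: bool = False,
) -> tuple[ImuRecording, GroundTruthLabel]:
    """Generate one recording: pre-idle + task template + post-idle.

    The ground-truth interval brackets exactly the task template.  With
    ``noiseless=True`` additive noise and idle sway are suppressed so the
    bare template (and the feature value it encodes) can be inspected.
    """
    task = Task(task)
    condition = Condition(condition)
    params = params or SynthParams()
    fs = params.sampling_rate_hz
    rng = np.random.default_rng(seed)

    n_pre = int(round(rng.uniform(*params.pre_idle_s) * fs))
    n_post = int(round(rng.uniform(*params.post_idle_s) * fs))

    # --- task template -------------------------------------------------
    generating_value: float
    if task is Task.TURN_360:
        mean, sd, lo, hi = params.turn_speed[condition]
        speed = float(_draw_clipped_normal(rng, mean, sd, lo, hi))
        duration = 360.0 / speed  # drawn value = average turning speed
        n_task = max(1, int(round(duration * fs)))
        tt = np.arange(n_task) / fs
        ramp = min(params.turn_ramp_s, duration / 3.0)
        plateau_speed = 360.0 / (duration - ramp)  # trapezoid area = 360 deg
        yaw = np.minimum(1.0, np.minimum(tt, duration - tt) / ramp)
        yaw = np.clip(yaw, 0.0, 1.0) * plateau_speed
        direction = -1.0 if rng.random() < 0.5 else 1.0
        if condition is Condition.DEVIATING and rng.random() < params.pause_prob:
            p_len = int(round(rng.uniform(*params.pause_duration_s) * fs))
            p_start = rng.integers(n_task // 4, max(n_task // 4 + 1, 3 * n_task // 4))
            yaw[p_start : p_start + p_len] = 0.0
        gyro_task = np.zeros((3, n_task))
        gyro_task[2] = direction * yaw
        accel_task = np.zeros((3, n_task))
        # stepping oscillation while turning
        accel_task[0] = 0.3 * np.sin(2.0 * np.pi * 1.2 * tt)
        accel_task[1] = 0.3 * np.sin(2.0 * np.pi * 1.2 * tt + np.pi / 3.0)
        generating_value = speed
    else:
        table = params.attempts[task][condition]
        k = _draw_categorical(rng, table)
        duration = rng.uniform(*params.task_duration_s)
        n_task = max(2 * k, int(round(duration * fs)))
        accel_task = np.zeros((3, n_task))
        gyro_task = np.zeros((3, n_task))
        sign = 1.0 if task is Task.SIT_TO_STAND else -1.0
        bounds = np.linspace(0, n_task, k + 1).astype(int)
        for j in range(k):
            seg = slice(bounds[j], bounds[j + 1])
            n_seg = bounds[j + 1] - bounds[j]
            tau = np.arange(n_seg) / max(n_seg - 1, 1)
            amp = rng.uniform(*params.ap_pulse_amp)
            accel_task[0, seg] = sign * amp * np.sin(2.0 * np.pi * tau)
            accel_task[2, seg] = sign * 0.6 * amp * np.sin(np.pi * tau)
            gyro_task[1, seg] = sign * 40.0 * np.sin(2.0 * np.pi * tau)
        generating_value = float(k)

    # --- assemble ------------------------------------------------------
    n_total = n_pre + n_task + n_post
    t = np.arange(n_total) / fs
    accel = np.zeros((3, n_total))
    gyro = np.zeros((3, n_total))
    accel[2] += 9.81  # gravity on the vertical axis; removed by detrending
    accel[:, n_pre : n_pre + n_task] += accel_task
    gyro[:, n_pre : n_pre + n_task] += gyro_task
    if not noiseless:
        for axis in (0, 1):
            idle_sway = _sway(rng, t, params.idle_sway_amp)
            idle_sway[n_pre : n_pre + n_task] = 0.0
            accel[axis] += idle_sway
        accel += rng.normal(0.0, params.noise_sd_accel, size=accel.shape)
        gyro += rng.normal(0.0, params.noise_sd_gyro, size=gyro.shape)

    rec = ImuRecording(
        subject_id=subject_id or f"synth-{task.value}-{seed}",
        task=task,
        time_s=t,
        accel=accel,
        gyro=gyro,
        sampling_rate_hz=fs,
    )
    interval = MotionInterval(
        start_s=n_pre / fs,
        end_s=(n_pre + n_task - 1) / fs,
        source=IntervalSource.GROUND_TRUTH,
    )
    full = FULL_MARKS[task]
    score = full if condition is Condition.NORMAL else int(rng.integers(0, full))
    label = GroundTruthLabel(
        interval=interval,
        task=task,
        tinetti_subscore=score,
        generating_value=generating_value,
    )
    return rec, label


def synth_cohort(
    task: Task | str,
    n_normal: int,
    n_deviating: int,
    params: SynthParams | None = None,
    seed: int = 0,
) -> list[tuple[ImuRecording, GroundTruthLabel]]:
    """Generate a cohort of independent subjects in seeded random order."""
    if n_normal < 0 or n_deviating < 0:
        raise ValidationError("cohort counts must be >= 0")
    n = n_normal + n_deviating
    if n == 0:
        raise ValidationError("cohort must contain at least one subject")
    rng = np.random.default_rng(seed)
    conditions = [Condition.NORMAL] * n_normal + [Condition.DEVIATING] * n_deviating
    order = rng.permutation(n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for i, idx in enumerate(order):
        rec, label = synth_recording(
            task,
            conditions[idx],
            params=params,
            seed=int(child_seeds[i]),
            subject_id=f"S{i + 1:03d}",
        )
        cohort.append((rec, label))
    return cohort


def synth_features(
    task: Task | str,
    n_normal: int,
    n_deviating: int,
    dists: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw feature values directly (no signals): i.i.d. per condition.

    ``dists`` maps each condition to either a categorical table
    ``{count: prob}`` (peak counts) or a ``(mean, sd, lo, hi)`` clipped
    normal (turning speeds).  Defaults follow the generator calibration
    for ``task``.  Returns ``(values, labels)`` in seeded random order.
    """
    task = Task(task)
    if n_normal < 0 or n_deviating < 0:
        raise ValidationError("counts must be >= 0")
    if n_normal + n_deviating == 0:
        raise ValidationError("need at least one subject")
    if dists is None:
        if task is Task.TURN_360:
            dists = dict(TURN_SPEED_DISTS)
        else:
            dists = {c: t for c, t in ATTEMPT_TABLES[task].items()}
    dists = {Condition(c): spec for c, spec in dists.items()}
    rng = np.random.default_rng(seed)
    values, labels = [], []
    for condition, count in (
        (Condition.NORMAL, n_normal),
        (Condition.DEVIATING, n_deviating),
    ):
        if count == 0:
            continue
        spec = dists.get(condition)
        if isinstance(spec, dict):
            _check_table(spec)
            draws = [_draw_categorical(rng, spec) for _ in range(count)]
        elif isinstance(spec, (tuple, list)) and len(spec) == 4:
            draws = np.atleast_1d(_draw_clipped_normal(rng, *spec, size=count))
        else:
            raise ValidationError(f"malformed distribution spec for {condition}")
        values.extend(float(v) for v in draws)
        labels.extend([condition] * count)
    order = rng.permutation(len(values))
    return np.asarray(values)[order], np.asarray(labels, dtype=object)[order]
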