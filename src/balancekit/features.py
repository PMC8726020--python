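"""Balance features extracted from a task interval.

Two scalar features, one per task family:

* sit-to-stand / stand-to-sit: the number of anterior-posterior
  acceleration peaks inside the interval.  A smooth transition shows a
  single AP thrust; multiple peaks indicate hesitation or repeated
  attempts to rise.  Peaks are counted on the detrended, signed AP
  signal, with height at least 45 % of the interval maximum and a
  0.2 s minimum separation.
* turning 360 deg: the average turning speed, i.e. |net vertical angular
  displacement| across the interval divided by its duration.  Slow
  turning is associated with balance impairment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig
from .preprocessing import PreprocessedSignals
from .types import MotionInterval, Task, ValidationError

__all__ = ["FeatureValue", "ap_peak_count", "mean_turn_speed", "extract_feature"]

#: minimum peak separation (s) for the AP peak count, consistent with the
#: postprocessing peak semantics
AP_PEAK_MIN_SEPARATION_S = 0.2


@dataclass
class FeatureValue:
    task: Task
    value: float  # peak count (integer-valued) or average speed in deg/s
    interval_used: MotionInterval


def _interval_slice(
    n: int, fs: float, time0: float, interval: MotionInterval
) -> slice:
    i0 = int(np.ceil((interval.start_s - time0) * fs - 1e-9))
    i1 = int(np.floor((interval.end_s - time0) * fs + 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, n - 1)
    if i1 < i0:
        raise ValidationError("interval covers no samples")
    return slice(i0, i1 + 1)


def ap_peak_count(
    accel_ap: np.ndarray,
    interval: MotionInterval,
    fs: float = 40.0,
    frac: float = 0.45,
    time0: float = 0.0,
) -> int:
    """Count AP acceleration peaks of height >= ``frac`` x interval max.

    ``accel_ap`` is the detrended AP channel of the whole recording; only
    the samples inside ``interval`` are considered.  The threshold is
    relative to the maximum of the restricted signal, so the count is
    invariant to positive rescaling.  An all-zero (or non-positive)
    segment yields 0.
    """
    accel_ap = np.asarray(accel_ap, dtype=float)
    seg = accel_ap[_interval_slice(accel_ap.size, fs, time0, interval)]
    top = seg.max()
    if top <= 0.0:
        return 0
    distance = max(1, int(round(AP_PEAK_MIN_SEPARATION_S * fs)))
    peaks, _ = find_peaks(seg, height=frac * top, distance=distance)
    return int(peaks.size)


def mean_turn_speed(
    ang_disp_vertical: np.ndarray,
    interval: MotionInterval,
    fs: float = 40.0,
    time0: float = 0.0,
) -> float:
    """|angular displacement change| / duration over the interval (deg/s)."""
    if interval.duration_s <= 0:
        raise ValidationError("interval must have positive duration")
    disp = np.asarray(ang_disp_vertical, dtype=float)
    sl = _interval_slice(disp.size, fs, time0, interval)
    return float(abs(disp[sl.stop - 1] - disp[sl.start])) / interval.duration_s


def extract_feature(
    pre: PreprocessedSignals,
    interval: MotionInterval,
    task: Task | str,
    cfg: PipelineConfig | None = None,
) -> FeatureValue:
    """Dispatch to the task's feature."""
    task = Task(task)
    cfg = cfg or PipelineConfig()
    t0 = float(pre.time_s[0])
    if task in (Task.SIT_TO_STAND, Task.STAND_TO_SIT):
        value = float(
            ap_peak_count(
                pre.accel_detrended[0],
                interval,
                fs=pre.sampling_rate_hz,
                frac=cfg.ap_peak_frac,
                time0=t0,
            )
        )
    elif task is Task.TURN_360:
        value = mean_turn_speed(
            pre.ang_disp[2], interval, fs=pre.sampling_rate_hz, time0=t0
        )
    else:  # pragma: no cover - Task() above rejects unknown names
        raise ValidationError(f"unknown task {task}")
    return FeatureValue(task=task, value=value, interval_used=interval)
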