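"""Signal conditioning and soft-labelled window segmentation.

Acceleration is detrended by removing the per-axis mean; angular velocity
is integrated (rectangle rule) into angular displacement from the start of
the recording, with no drift correction (tasks last well under 30 s and
the sensor class drifts at ~0.05 deg/s).  The six conditioned channels are
then cut into 0.75 s sliding windows; when a ground-truth interval is
available each window carries a soft label: the fraction of the window's
time span covered by the task vs non-task classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import ImuRecording, MotionInterval, ValidationError

__all__ = [
    "PreprocessedSignals",
    "WindowSegment",
    "detrend_accel",
    "integrate_gyro",
    "preprocess",
    "make_window_arrays",
    "make_windows",
]


@dataclass
class PreprocessedSignals:
    """Detrended acceleration (m/s^2) and angular displacement (deg)."""

    accel_detrended: np.ndarray  # 3 x T, zero-mean per axis
    ang_disp: np.ndarray  # 3 x T, cumulative degrees, ang_disp[:, 0] = 0
    time_s: np.ndarray
    sampling_rate_hz: float

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    def channels(self) -> np.ndarray:
        """T x 6 matrix: detrended accel (AP, ML, V) + angular displacement."""
        return np.vstack([self.accel_detrended, self.ang_disp]).T


@dataclass
class WindowSegment:
    samples: np.ndarray  # W x 6
    center_time_s: float
    soft_label: tuple[float, float] | None = None  # (p_task, p_nontask)


def detrend_accel(rec: ImuRecording) -> np.ndarray:
    """Subtract the per-axis mean from the acceleration channels."""
    return rec.accel - rec.accel.mean(axis=1, keepdims=True)


def integrate_gyro(rec: ImuRecording) -> np.ndarray:
    """Cumulative angular displacement (deg) per axis, anchored at zero.

    Left-rectangle rule with dt = 1/fs: ``disp[i] = dt * sum_{j<i} omega[j]``.
    """
    dt = 1.0 / rec.sampling_rate_hz
    disp = np.zeros_like(rec.gyro)
    disp[:, 1:] = np.cumsum(rec.gyro[:, :-1], axis=1) * dt
    return disp


def preprocess(rec: ImuRecording) -> PreprocessedSignals:
    return PreprocessedSignals(
        accel_detrended=detrend_accel(rec),
        ang_disp=integrate_gyro(rec),
        time_s=rec.time_s.copy(),
        sampling_rate_hz=rec.sampling_rate_hz,
    )


def _soft_labels(
    window_starts_s: np.ndarray, window_s: float, truth: MotionInterval
) -> np.ndarray:
    """p_task per window = overlap of [t0, t0 + window_s] with the truth
    interval, as a fraction of the window span (continuous time)."""
    lo = np.maximum(window_starts_s, truth.start_s)
    hi = np.minimum(window_starts_s + window_s, truth.end_s)
    return np.clip(hi - lo, 0.0, None) / window_s


def make_window_arrays(
    pre: PreprocessedSignals,
    truth: MotionInterval | None,
    window_s: float = 0.75,
    step_s: float = 0.025,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Vectorised segmentation.

    Returns ``(X, y, centers)`` where ``X`` is N x W x 6, ``y`` is the
    N x 2 soft-label matrix ``(p_task, p_nontask)`` (``None`` without
    ground truth) and ``centers`` the window centre times in seconds.
    Windows advance by ``step_s`` (>= one sample); a partial trailing
    window is dropped.
    """
    fs = pre.sampling_rate_hz
    w = int(round(window_s * fs))
    if w < 1:
        raise ValidationError("window shorter than one sample")
    step = max(1, int(round(step_s * fs)))
    t = pre.n_samples
    if t < w:
        raise ValidationError(f"recording ({t} samples) shorter than window ({w})")
    channels = pre.channels()  # T x 6
    view = sliding_window_view(channels, w, axis=0)  # (T-w+1) x 6 x W
    x = view[::step].transpose(0, 2, 1)  # N x W x 6
    starts_s = pre.time_s[np.arange(0, t - w + 1, step)]
    centers = starts_s + window_s / 2.0
    y = None
    if truth is not None:
        p_task = _soft_labels(starts_s, window_s, truth)
        y = np.column_stack([p_task, 1.0 - p_task])
    return np.ascontiguousarray(x, dtype=float), y, centers


def make_windows(
    pre: PreprocessedSignals,
    truth: MotionInterval | None,
    window_s: float = 0.75,
    step_s: float = 0.025,
) -> list[WindowSegment]:
    """Object view of :func:`make_window_arrays`."""
    x, y, centers = make_window_arrays(pre, truth, window_s, step_s)
    out = []
    for i in range(x.shape[0]):
        label = None if y is None else (float(y[i, 0]), float(y[i, 1]))
        out.append(WindowSegment(x[i], float(centers[i]), label))
    return out
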