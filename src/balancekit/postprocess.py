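"""Turn a noisy probability trace into one motion interval.

The raw per-window detector output is mean-filtered (1 / 1.25 / 1.5 s),
then candidate intervals are anchored on non-task probability peaks:

* begin: the closest peak of non-task probability before the point where
  task probability starts to exceed 0.5;
* end: the first peak of non-task probability after the point where task
  probability starts to fall below 0.5.

Peaks are strict local maxima of height >= 0.5 *and* prominence >= 0.5,
with a minimum separation of 0.25 s (plateaus count once, at their
midpoint).  The prominence requirement makes a qualifying peak a genuine
return to non-task behaviour — e.g. the gap between two task
excursions — rather than a float-level wiggle of the smoothed idle
plateau, which would otherwise drag every anchor about half the
window-plus-filter width outside the true boundary.  Anchor peaks are
searched between the current excursion and its neighbours, so candidates
stay time-ordered and non-overlapping.  When a side has no qualifying
peak (the usual case for a clean single-task recording) the crossing
time itself is used and the interval is flagged degenerate.  If several candidates survive, task-specific rules pick one:
greatest AP acceleration range for the sit/stand transitions, and for
turning the candidate with the greatest cumulative yaw below the
360-degree limit (plus a 5 % integration-error allowance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig
from .detector import MotionDetector, ProbabilityTrace
from .preprocessing import PreprocessedSignals, preprocess
from .types import ImuRecording, IntervalSource, MotionInterval, Task, ValidationError

__all__ = [
    "CandidateIntervalSet",
    "smooth_trace",
    "candidate_intervals",
    "select_interval",
    "detect_motion",
]


@dataclass
class CandidateIntervalSet:
    intervals: list[MotionInterval]
    trace_used: ProbabilityTrace


def smooth_trace(trace: ProbabilityTrace, mean_filter_s: float) -> ProbabilityTrace:
    """Centred moving average of both channels, truncated at the edges.

    Edge windows average only the samples that exist (renormalised), and
    the output is renormalised so the two channels still sum to one.
    """
    step = trace.step_s
    if step <= 0:
        raise ValidationError("trace too short to smooth")
    n = int(round(mean_filter_s / step))
    if n < 1:
        raise ValidationError("mean filter shorter than one trace step")
    if n > len(trace):
        raise ValidationError("mean filter longer than the trace")
    kernel = np.ones(n)
    counts = np.convolve(np.ones(len(trace)), kernel, mode="same")
    p_task = np.convolve(trace.p_task, kernel, mode="same") / counts
    p_non = np.convolve(trace.p_nontask, kernel, mode="same") / counts
    total = p_task + p_non
    return ProbabilityTrace(trace.center_times_s.copy(), p_task / total, p_non / total)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def candidate_intervals(
    trace: ProbabilityTrace,
    prob_threshold: float = 0.5,
    peak_height: float = 0.5,
    peak_prominence: float = 0.5,
    min_separation_s: float = 0.25,
) -> CandidateIntervalSet:
    """Apply the begin/end anchoring rules to a smoothed trace."""
    times = trace.center_times_s
    n = len(trace)
    if n == 0:
        return CandidateIntervalSet([], trace)
    step = trace.step_s or 1.0
    distance = max(1, int(round(min_separation_s / step)))
    peaks, _ = find_peaks(
        trace.p_nontask,
        height=peak_height,
        prominence=peak_prominence,
        distance=distance,
    )
    runs = _runs_above(trace.p_task > prob_threshold)
    intervals: list[MotionInterval] = []
    for i, (s, e) in enumerate(runs):
        lo_bound = runs[i - 1][1] if i > 0 else -1  # previous run's last index
        hi_bound = runs[i + 1][0] if i + 1 < len(runs) else n  # next run's first
        degenerate = False
        before = peaks[(peaks > lo_bound) & (peaks < s)]
        if before.size:
            start_t = times[before[-1]]
        else:
            start_t = times[s]
            degenerate = True
        after = peaks[(peaks > e) & (peaks < hi_bound)]
        if after.size:
            end_t = times[after[0]]
        else:
            end_t = times[min(e + 1, n - 1)]
            degenerate = True
        if end_t <= start_t:  # single-window run at the trace edge
            end_t = start_t + 0.5 * step
            degenerate = True
        intervals.append(
            MotionInterval(
                start_s=float(start_t),
                end_s=float(end_t),
                source=IntervalSource.DETECTED,
                degenerate_flag=degenerate,
            )
        )
    return CandidateIntervalSet(intervals, trace)


def _slice_indices(
    pre: PreprocessedSignals, interval: MotionInterval
) -> tuple[int, int]:
    i0 = int(np.searchsorted(pre.time_s, interval.start_s - 1e-9, side="left"))
    i1 = int(np.searchsorted(pre.time_s, interval.end_s + 1e-9, side="right")) - 1
    i0 = min(max(i0, 0), pre.n_samples - 1)
    i1 = min(max(i1, i0), pre.n_samples - 1)
    return i0, i1


def ap_range(pre: PreprocessedSignals, interval: MotionInterval) -> float:
    """Range (max - min) of detrended AP acceleration within the interval."""
    i0, i1 = _slice_indices(pre, interval)
    seg = pre.accel_detrended[0, i0 : i1 + 1]
    return float(seg.max() - seg.min())


def cumulative_turn(pre: PreprocessedSignals, interval: MotionInterval) -> float:
    """|net vertical angular movement| (deg) from the interval's start."""
    i0, i1 = _slice_indices(pre, interval)
    return float(abs(pre.ang_disp[2, i1] - pre.ang_disp[2, i0]))


def select_interval(
    candidates: CandidateIntervalSet,
    pre: PreprocessedSignals,
    task: Task | str,
    turn_limit_deg: float = 360.0,
    turn_tolerance: float = 1.05,
) -> MotionInterval:
    """Reduce a candidate set to the single task interval."""
    task = Task(task)
    ivals = candidates.intervals
    if not ivals:
        return MotionInterval(
            start_s=float(pre.time_s[0]),
            end_s=float(pre.time_s[-1]),
            source=IntervalSource.DETECTED,
            degenerate_flag=True,
        )
    if len(ivals) == 1:
        return ivals[0]
    if task in (Task.SIT_TO_STAND, Task.STAND_TO_SIT):
        return max(ivals, key=lambda iv: ap_range(pre, iv))
    # turning: candidates whose cumulative yaw stays below the limit
    # (+ tolerance); among them, the one with the greatest movement.
    limit = turn_limit_deg * turn_tolerance
    moves = [(cumulative_turn(pre, iv), iv) for iv in ivals]
    admissible = [(m, iv) for m, iv in moves if m <= limit]
    if admissible:
        return max(admissible, key=lambda t: t[0])[1]
    # no candidate below the limit: fall back to the one closest to a
    # full turn and flag it
    best = min(moves, key=lambda t: abs(t[0] - turn_limit_deg))[1]
    best.degenerate_flag = True
    return best


def detect_motion(
    rec: ImuRecording,
    detector: MotionDetector,
    cfg: PipelineConfig | None = None,
) -> MotionInterval:
    """Full detection chain for one recording."""
    cfg = cfg or PipelineConfig()
    pre = preprocess(rec)
    trace = detector.predict_trace(pre, cfg.window_s, cfg.step_s)
    smoothed = smooth_trace(trace, cfg.mean_filter_s)
    cands = candidate_intervals(
        smoothed,
        prob_threshold=cfg.prob_threshold,
        peak_height=cfg.peak_height_threshold,
        peak_prominence=cfg.peak_prominence,
        min_separation_s=cfg.peak_min_separation_s,
    )
    return select_interval(
        cands, pre, rec.task, cfg.turn_limit_deg, cfg.turn_tolerance
    )
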