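"""Trace smoothing, interval rules (vs a brute-force oracle), selection."""

import numpy as np
import pytest

from balancekit import (
    MotionInterval,
    ProbabilityTrace,
    ValidationError,
    candidate_intervals,
    detect_motion,
    select_interval,
    smooth_trace,
    synth_recording,
)
from balancekit.assessment import detection_accuracy
from balancekit.postprocess import CandidateIntervalSet
from balancekit.preprocessing import PreprocessedSignals, preprocess

STEP = 0.025


def trace_from(p_task: np.ndarray, step: float = STEP) -> ProbabilityTrace:
    p_task = np.asarray(p_task, dtype=float)
    times = np.arange(p_task.size) * step + 0.375
    return ProbabilityTrace(times, p_task, 1.0 - p_task)


# --------------------------------------------------------------------------
# independent brute-force implementation of the interval rules
# --------------------------------------------------------------------------


def oracle_peaks(x: np.ndarray, height: float, prominence: float, distance: int):
    """Literal scan: strict local maxima (plateau midpoint), height,
    greedy highest-first minimum separation, prominence by definition."""
    n = x.size
    maxima = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                maxima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    maxima = [m for m in maxima if x[m] >= height]
    # min-separation: keep larger peaks first
    keep = np.ones(len(maxima), dtype=bool)
    order = sorted(range(len(maxima)), key=lambda k: x[maxima[k]], reverse=True)
    for k in order:
        if not keep[k]:
            continue
        for other in range(len(maxima)):
            if other != k and keep[other] and abs(maxima[other] - maxima[k]) < distance:
                if x[maxima[other]] <= x[maxima[k]]:
                    keep[other] = False
    maxima = [m for k, m in enumerate(maxima) if keep[k]]
    # prominence by definition: lowest contour line to a higher point
    out = []
    for m in maxima:
        left = m
        left_min = x[m]
        while left > 0 and x[left - 1] <= x[m]:
            left -= 1
            left_min = min(left_min, x[left])
        right = m
        right_min = x[m]
        while right < n - 1 and x[right + 1] <= x[m]:
            right += 1
            right_min = min(right_min, x[right])
        if x[m] - max(left_min, right_min) >= prominence:
            out.append(m)
    return out


def oracle_candidates(trace: ProbabilityTrace, thr=0.5, height=0.5, prom=0.5,
                      min_sep_s=0.25):
    x = trace.p_task
    times = trace.center_times_s
    n = x.size
    distance = max(1, int(round(min_sep_s / trace.step_s)))
    peaks = oracle_peaks(trace.p_nontask, height, prom, distance)
    above = x > thr
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n - 1 and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    intervals = []
    for r, (s, e) in enumerate(runs):
        lo = runs[r - 1][1] if r > 0 else -1
        hi = runs[r + 1][0] if r + 1 < len(runs) else n
        degenerate = False
        before = [p for p in peaks if lo < p < s]
        start_t = times[before[-1]] if before else times[s]
        degenerate |= not before
        after = [p for p in peaks if e < p < hi]
        end_t = times[after[0]] if after else times[min(e + 1, n - 1)]
        degenerate |= not after
        if end_t <= start_t:
            end_t = start_t + 0.5 * trace.step_s
            degenerate = True
        intervals.append((start_t, end_t, degenerate))
    return intervals


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        trace = trace_from(np.full(100, 0.3))
        out = smooth_trace(trace, 1.0)
        np.testing.assert_allclose(out.p_task, 0.3, atol=1e-12)

    def test_interior_impulse_becomes_one_over_n(self):
        p = np.zeros(200)
        p[100] = 1.0
        out = smooth_trace(trace_from(p), 1.0)  # n = 40 steps
        assert out.p_task.max() == pytest.approx(1.0 / 40.0)

    def test_step_trace_hand_computed(self):
        p = np.r_[np.zeros(100), np.ones(100)]
        n = 9  # 0.225 s filter -> odd window
        out = smooth_trace(trace_from(p), 0.225)
        h = n // 2
        # centred window at the last zero / first one of the step
        assert out.p_task[99] == pytest.approx(h / n)
        assert out.p_task[100] == pytest.approx((h + 1) / n)

    def test_smoothing_preserves_normalisation_and_range(self, rng):
        p = rng.uniform(0, 1, 300)
        out = smooth_trace(trace_from(p), 1.25)
        np.testing.assert_allclose(out.p_task + out.p_nontask, 1.0, atol=1e-12)
        assert out.p_task.min() >= p.min() - 1e-12
        assert out.p_task.max() <= p.max() + 1e-12

    def test_filter_longer_than_trace_rejected(self):
        with pytest.raises(ValidationError):
            smooth_trace(trace_from(np.zeros(10)), 1.0)


class TestCandidateRules:
    def test_single_excursion_with_prominent_anchors(self):
        # p_task ~0.1 before 3.5 s, ~1 on (3.5, 6.5), ~0.1 after; nontask
        # has genuine dips nearby so the anchors at 3.2 s and 6.8 s qualify
        times = np.arange(0.375, 12, STEP)
        p = np.full_like(times, 0.1)
        p[(times > 2.0) & (times < 3.0)] = 0.5  # nontask dip (not a run)
        p[(times > 7.0) & (times < 8.0)] = 0.5
        p[np.abs(times - 3.2) < 0.013] = 0.0  # nontask peaks of prominence 0.5
        p[np.abs(times - 6.8) < 0.013] = 0.0
        p[(times > 3.5) & (times < 6.5)] = 1.0
        cands = candidate_intervals(trace_from(p)).intervals
        assert len(cands) == 1
        assert cands[0].start_s == pytest.approx(3.2)
        assert cands[0].end_s == pytest.approx(6.8)
        assert not cands[0].degenerate_flag

    def test_no_crossing_gives_empty_set(self):
        trace = trace_from(np.full(200, 0.4))
        assert candidate_intervals(trace).intervals == []

    def test_two_excursions_ordered(self):
        p = np.zeros(400)
        p[80:140] = 1.0
        p[260:320] = 1.0
        cands = candidate_intervals(trace_from(p)).intervals
        assert len(cands) == 2
        assert cands[0].end_s <= cands[1].start_s

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_traces(self, seed):
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(40, 500))
            raw = rng.uniform(0, 1, n)
            p = np.clip(
                gaussian_filter1d(raw, sigma=float(rng.uniform(1, 8)))
                * float(rng.uniform(0.9, 1.8)),
                0.0,
                1.0,
            )
            trace = trace_from(p)
            got = candidate_intervals(trace).intervals
            expected = oracle_candidates(trace)
            assert len(got) == len(expected)
            for iv, (s, e, d) in zip(got, expected):
                assert iv.start_s == pytest.approx(s, abs=1e-9)
                assert iv.end_s == pytest.approx(e, abs=1e-9)
                assert iv.degenerate_flag == d


def signals_from(ap=None, yaw_disp=None, fs=40.0):
    n = len(ap) if ap is not None else len(yaw_disp)
    accel = np.zeros((3, n))
    disp = np.zeros((3, n))
    if ap is not None:
        accel[0] = np.asarray(ap, dtype=float)
        accel -= accel.mean(axis=1, keepdims=True)
    if yaw_disp is not None:
        disp[2] = yaw_disp
    return PreprocessedSignals(
        accel_detrended=accel, ang_disp=disp, time_s=np.arange(n) / fs,
        sampling_rate_hz=fs,
    )


def interval(a, b):
    return MotionInterval(a, b, source="detected")


class TestSelectInterval:
    def test_sit_to_stand_takes_greatest_ap_range(self):
        ap = np.zeros(400)
        ap[40:80] = np.r_[np.linspace(0, 2.0, 20), np.linspace(2.0, 0, 20)]
        ap[200:240] = np.r_[np.linspace(0, 5.0, 20), np.linspace(5.0, 0, 20)]
        pre = signals_from(ap=ap)
        cands = CandidateIntervalSet([interval(0.9, 2.1), interval(4.9, 6.1)], None)
        chosen = select_interval(cands, pre, "sit_to_stand")
        assert chosen.start_s == pytest.approx(4.9)

    def test_turning_takes_largest_admissible_turn(self):
        # cumulative yaw 350 deg in the first candidate, 710 deg in a
        # candidate spanning both excursions
        yaw = np.r_[np.linspace(0, 350, 200), np.linspace(350, 710, 200)]
        pre = signals_from(yaw_disp=yaw)
        cands = CandidateIntervalSet([interval(0.01, 4.9), interval(0.01, 9.9)], None)
        chosen = select_interval(cands, pre, "turn_360")
        assert chosen.end_s == pytest.approx(4.9)

    def test_single_candidate_returned_unchanged(self):
        pre = signals_from(ap=np.zeros(100))
        only = interval(0.5, 1.5)
        assert select_interval(CandidateIntervalSet([only], None), pre, "turn_360") is only

    def test_order_invariance(self):
        ap = np.zeros(400)
        ap[40:80] = 2.0
        ap[200:240] = 5.0
        pre = signals_from(ap=ap)
        a = select_interval(
            CandidateIntervalSet([interval(0.9, 2.1), interval(4.9, 6.1)], None),
            pre, "stand_to_sit",
        )
        b = select_interval(
            CandidateIntervalSet([interval(4.9, 6.1), interval(0.9, 2.1)], None),
            pre, "stand_to_sit",
        )
        assert (a.start_s, a.end_s) == (b.start_s, b.end_s)

    def test_empty_candidates_fall_back_to_whole_recording(self):
        pre = signals_from(ap=np.zeros(100))
        out = select_interval(CandidateIntervalSet([], None), pre, "sit_to_stand")
        assert out.degenerate_flag
        assert out.start_s == pytest.approx(0.0)
        assert out.end_s == pytest.approx(pre.time_s[-1])


class TestDetectMotion:
    def test_held_out_recording_detected_accurately(self, sit_detector, sit_cohort, cfg):
        rec, label = sit_cohort[-1]  # S006, never trained on
        detected = detect_motion(rec, sit_detector, cfg)
        acc = detection_accuracy(detected, label.interval, rec.duration_s, 40.0)
        assert acc > 0.85

    def test_idle_only_recording_is_degenerate(self, sit_detector, cfg):
        rec, _ = synth_recording("sit_to_stand", "normal", seed=99)
        rec.accel[:, :] = rec.accel[:, :1]
        rec.gyro[:, :] = 0.0
        rng = np.random.default_rng(6)
        rec.accel += rng.normal(0, 0.05, rec.accel.shape)
        rec.gyro += rng.normal(0, 1.0, rec.gyro.shape)
        detected = detect_motion(rec, sit_detector, cfg)
        assert detected.degenerate_flag

    def test_detection_is_deterministic(self, sit_detector, sit_cohort, cfg):
        rec, _ = sit_cohort[2]
        a = detect_motion(rec, sit_detector, cfg)
        b = detect_motion(rec, sit_detector, cfg)
        assert (a.start_s, a.end_s) == (b.start_s, b.end_s)
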