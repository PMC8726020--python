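# Methods

## Problem setting

A subject wears a 6-channel IMU (tri-axial accelerometer in m/s², tri-axial
gyroscope in °/s, 40 Hz) on the lower back and performs exactly one known
balance task per recording: sit-to-stand, a 360° turn, or stand-to-sit.
Recordings start before the task and end after it, so each contains
pre-task and post-task non-task signal. The pipeline answers two
questions per recording: *when* did the task happen, and does the
subject's execution *deviate from healthy* in the sense of scoring below
full marks on the corresponding Tinetti POMA-B items (4 for
sit-to-stand, 2 for turning and stand-to-sit).

Axis convention: channels are ordered anterior-posterior (AP),
medio-lateral (ML), vertical; the vertical axis is the yaw/turning axis.
Time is 0-based seconds; intervals are closed `[start_s, end_s]`.

## Preprocessing

Acceleration is detrended by subtracting the per-axis mean (this also
removes gravity from the vertical channel). Angular velocity is
integrated into angular displacement from the recording start by the
left-rectangle rule with Δt = 1/fs; gyroscope drift is not corrected
(tasks last well under 30 s and the sensor class drifts at ~0.05 °/s).
The six conditioned channels are cut into sliding windows of
0.75 s (30 samples) advancing by one sample (0.025 s). A stated step of
0.03 s is not an integer number of samples at 40 Hz; one sample is the
closest realizable step and is the default (configurable).

Each training window carries a *soft label*: the fraction of its time
span covered by the task interval vs non-task, computed in continuous
time (a window with 0.5 s task and 0.25 s non-task is labelled
(0.67, 0.33)). Partial trailing windows are dropped so the detector
input shape is fixed.

## Motion detector

A binary window classifier: 1-D convolution over time with 32 filters of
kernel 3 (ReLU), an LSTM (default width 32), then dense layers
(64, 32, 2); the first dense layers apply no activation and the last is
a 2-way softmax giving (p_task, p_nontask). A single convolution layer
is used, with a configuration hook for the widths. Channels are
standardized per channel with training-set statistics stored on the
model.

Training minimises cross-entropy against the soft two-vector targets
with Adam (lr 1e-3), mini-batches of 200 windows, fully seeded and
single-threaded (identical seeds give identical runs). 10 % of training
*subjects* (at least one) are held out to monitor validation loss;
training stops when it has not improved for 20 consecutive epochs (or at
`max_epochs`, default 60) and the best weights are restored. Since no
deep-learning framework is part of the dependency set, the network —
forward pass, backpropagation through time, Adam — is implemented in
numpy (`_network.py`) and verified against central finite differences in
the test suite.

Training windows advance by 0.1 s rather than the 0.025 s inference
step: adjacent inference-step windows overlap by >95 % and are nearly
redundant for fitting, so the coarser stride keeps the training set
compact (configurable via `DetectorConfig.train_step_s`). The LSTM and
dense widths are the smallest that solve the synthetic detection task
robustly; all are configurable.

Evaluation uses leave-one-subject-out cross-validation: for each
subject, a fresh detector is trained on every other subject's windows
and applied to the held-out recording only, preventing subject-identity
leakage. The fold audit (held-out subject absent from its own training
fold) is asserted in the tests.

## Postprocessing: from trace to interval

The raw per-window trace is noisy, so it is smoothed with a centred
mean filter of 1 s (1.25 s and 1.5 s are also supported); edge windows
are truncated and renormalised, and the two channels are renormalised to
sum to one. Candidate intervals are then anchored:

* **begin** — the closest qualifying peak of non-task probability before
  the point where task probability starts to exceed 0.5;
* **end** — the first qualifying peak of non-task probability after the
  point where task probability starts to fall below 0.5.

A qualifying peak is a strict local maximum (plateaus count once, at
their midpoint) with height ≥ 0.5 **and prominence ≥ 0.5**, with at
least 0.25 s separation. The prominence requirement is the package's
interpretation of "peak detection with 0.5 thresholds": without it, the
smoothed non-task probability is a ~1.0 plateau outside the task whose
float-level wiggles all count as peaks, and the anchors attach to noise
roughly half the window-plus-filter width (~0.9 s) outside each true
boundary, capping per-sample detection accuracy near 0.80 for
sit/stand-length recordings. With it, a qualifying peak is a genuine
return to non-task behaviour — exactly what separates two task
excursions — and on clean single-excursion traces the rule falls back to
the 0.5-crossing time itself, flagged `degenerate` (fallback used).
Anchors are searched between the current excursion and its neighbours,
keeping candidates ordered and non-overlapping.

If several candidates survive, the task rule picks one: for
sit-to-stand / stand-to-sit the candidate with the greatest AP
acceleration range; for turning, among candidates whose cumulative
vertical angular movement from their start is below 360° (plus a 5 %
allowance for integration and boundary error, i.e. ≤ 378°,
configurable), the one with the greatest movement. With no admissible
turning candidate, the one closest to a full turn is used and flagged;
with no candidates at all, the whole recording is returned flagged
degenerate so downstream assessment always runs.

## Features and classification

* `ap_peak_count`: local maxima of the detrended, signed AP acceleration
  restricted to the interval, with height ≥ 45 % of the restricted
  signal's maximum and ≥ 0.2 s separation; positive peaks only (the
  sit-to-stand AP signature is a positive thrust; a rectified mode is a
  configuration choice away). All-zero/non-positive segments count 0.
  The relative threshold makes the count invariant to positive
  rescaling.
* `mean_turn_speed`: |angular displacement at interval end − at start| /
  duration, sign-invariant.

Subjects are classified from the single feature value, standardized with
training-fold statistics:

* **one-class SVM** (RBF, ν = 0.1, sklearn's scale bandwidth), trained
  on the *normal* class only; score = negated decision function. The
  margin itself counts as inside: discrete peak-count features put most
  training mass on one value, which libsvm places exactly on the learned
  boundary; counting it as an outlier would flag 100 % of training
  normals and void the ν ≤ 0.1 training-outlier bound.
* **LDA**; score = posterior probability of deviating.
* **k-NN** (k = 5, Euclidean distance on the standardized feature,
  distance ties broken by smaller training index via a stable sort);
  score = fraction of deviating neighbours.

All three are always computed by the evaluation report; no silent
best-model selection. LOSO pooling gives the confusion counts, accuracy,
and AUC (Mann-Whitney rank formulation, ties as ½). Agreement between
the manual-interval and detected-interval pipelines uses McNemar's
z² = (n₁₂−n₂₁)²/(n₁₂+n₂₁) against χ²(1), with z² = 0, p = 1 declared
degenerate when there are no discordant pairs, plus paired feature
differences (mean difference and Wilcoxon signed-rank). No
multiple-testing correction is applied.

## Synthetic data generator

The generator stands in for the undeposited 59-subject cohort. Each
recording is pre-idle (uniform 2–6 s) + task template + post-idle
(uniform 1–3 s) at 40 Hz, with gravity on the vertical accelerometer
axis, low-frequency postural sway (0.1 m/s², 0.2–0.5 Hz) on the
horizontal axes during idle, and additive white Gaussian noise
(0.05 m/s² accelerometer, 1 °/s gyroscope). Templates are parametric,
not resampled human motion, so Bayes separability is controllable:

* *Sit/stand transitions* (uniform 1.5–3.5 s): k biphasic AP sine pulses
  of amplitude uniform 1.5–2.5 m/s² (stand-to-sit is the mirror image),
  with matching vertical-acceleration humps and a pitch angular-velocity
  pulse. k is the number of attempts, drawn per condition:
  sit-to-stand {1: 0.95, 2: 0.05} normal vs
  {1: 0.20, 2: 0.40, 3: 0.25, 4: 0.15} deviating (implied mean 2.35);
  stand-to-sit {1: 0.97, 2: 0.03} vs {1: 0.35, 2: 0.50, 3: 0.15}. These
  tables place the implied peak-count means near the reported cohort
  statistics (healthy ≈ 1.0; deviating ≈ 2.46 and 1.54).
* *Turning* : trapezoidal yaw velocity (0.5 s ramps, random direction)
  whose cumulative displacement is exactly 360°. The drawn value is the
  **average** turning speed — normal 58.16 (19.22) °/s clipped to
  [20, 100] for healthy, 23.46 (13.96) clipped to [8, 60] for
  deviating (clipping keeps the configured mean calibrated) — and
  the template duration is 360°/speed, so the extracted feature
  recovers the draw directly. Optional mid-turn pauses (velocity dips to
  0 for 0.3–1 s) emulate non-continuous turns; off by default.

The ground-truth interval brackets the template exactly, with ≥ 1 s of
idle on each side. Everything is driven by `numpy` generators seeded
from a single integer; identical seeds give bitwise-identical cohorts.
What the generator does **not** model: biomechanically validated motion,
soft-tissue artifacts, sensor misalignment, gyro drift, and real raw
signal amplitudes (the templates' amplitudes are plausible values, not
calibrated against hardware). Benchmarks on these signals therefore
bound what the pipeline can do on clean, well-separated data; field
recordings are harder.

## Benchmark problem sizes

The detection benchmark uses 12-subject cohorts (9 normal, 3 deviating,
the cohort-level class ratio) per task with full LOSO — 12 detector
trainings per task; the classification benchmark uses 50 Monte-Carlo
feature cohorts of 59 subjects with the reported class splits (45:14)
per repetition. These sizes give stable means while keeping a complete
run in minutes on a single CPU.

## Numerical conventions and edge cases

* Window length = round(0.75·fs) = 30 samples; mean-filter length =
  round(filter/step) trace steps; both must be ≥ 1.
* A run of p_task > 0.5 touching the trace edge falls back to the edge
  sample; a single-window run at the very edge is given a half-step
  extent and flagged.
* Per-sample detection accuracy is indicator agreement on the uniform
  40 Hz grid over the whole recording, closed intervals at both ends.
* `mcnemar(0, 0)` is defined as z² = 0, p = 1 with a degenerate note;
  negative counts are rejected.
* Empty/zero-signal guards: all-zero AP segments count 0 peaks;
  single-class training sets, empty cohorts, reversed intervals and
  out-of-range thresholds raise validation errors rather than
  propagating NaNs.

## Known limitations

* The detector is binary and per-task; recognising which of many tasks
  occurs in an unsegmented stream is out of scope.
* The synthetic benchmark is cleaner than field data; accuracies on it
  are upper bounds, not estimates of clinical performance.
* One recording is assumed to contain exactly one prevailing task
  motion; overlapping or repeated tasks are resolved by the selection
  rules, not detected separately.
* Features are single scalars by design; richer feature sets (jerk,
  spectral sway measures) are deliberately not included.
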