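"""Conv-LSTM motion detector: build, train, predict, and the LOSO harness.

The detector is a binary window classifier (task vs non-task) over 0.75 s
six-channel windows.  Training minimises soft-target cross-entropy with
Adam, mini-batches of 200 windows, and stops once a held-out validation
loss (10 % of training subjects) has not improved for 20 consecutive
epochs, restoring the best weights.  All randomness flows from the
configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._network import Adam, ConvLstmNet, EarlyStopping, soft_cross_entropy
from .config import DetectorConfig, PipelineConfig
from .preprocessing import PreprocessedSignals, make_window_arrays, preprocess
from .types import GroundTruthLabel, ImuRecording, ValidationError

__all__ = [
    "DetectorConfig",
    "ProbabilityTrace",
    "MotionDetector",
    "StateError",
    "build_detector",
    "train_detector",
    "predict_trace",
    "loso_train_predict",
]


class StateError(RuntimeError):
    """Raised when an operation requires a trained detector."""


@dataclass
class ProbabilityTrace:
    """Per-window (p_task, p_nontask) indexed by window centre time."""

    center_times_s: np.ndarray
    p_task: np.ndarray
    p_nontask: np.ndarray

    def __post_init__(self) -> None:
        self.center_times_s = np.asarray(self.center_times_s, dtype=float)
        self.p_task = np.asarray(self.p_task, dtype=float)
        self.p_nontask = np.asarray(self.p_nontask, dtype=float)
        n = self.center_times_s.size
        if self.p_task.size != n or self.p_nontask.size != n:
            raise ValidationError("trace arrays must have equal length")
        if n and np.any(np.abs(self.p_task + self.p_nontask - 1.0) > 1e-6):
            raise ValidationError("p_task + p_nontask must equal 1 elementwise")

    def __len__(self) -> int:
        return self.center_times_s.size

    @property
    def step_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.median(np.diff(self.center_times_s)))


@dataclass
class MotionDetector:
    """A conv-LSTM window classifier plus its input standardisation."""

    cfg: DetectorConfig
    window_len: int = 30
    n_channels: int = 6
    net: ConvLstmNet | None = None
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None
    trained: bool = False
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.net is None:
            self.net = ConvLstmNet(
                n_channels=self.n_channels,
                window_len=self.window_len,
                conv_filters=self.cfg.conv_filters,
                kernel_size=self.cfg.kernel_size,
                lstm_units=self.cfg.lstm_units,
                dense_sizes=self.cfg.dense_sizes,
                seed=self.cfg.seed,
            )

    # ---- training ----------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean) / self.norm_std

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray | None = None,
        seed: int | None = None,
    ) -> dict:
        """Train on N x W x C windows with N x 2 soft labels.

        ``groups`` carries the subject id per window; the validation split
        holds out whole subjects so early stopping never sees training
        subjects.  Returns the training log (also kept on the detector).
        """
        cfg = self.cfg
        x = np.asarray(x)
        y = np.asarray(y, dtype=float)
        if x.ndim != 3 or x.shape[0] != y.shape[0]:
            raise ValidationError("x must be N x W x C aligned with y")
        hard = y[:, 0] > 0.5
        if hard.all() or (~hard).all():
            raise ValidationError(
                "training windows must include both task and non-task examples"
            )
        rng = np.random.default_rng(cfg.seed if seed is None else seed)

        # per-channel standardisation from the training windows
        self.norm_mean = x.mean(axis=(0, 1), keepdims=True)
        self.norm_std = x.std(axis=(0, 1), keepdims=True)
        self.norm_std[self.norm_std < 1e-8] = 1.0
        xs = self._standardize(x).astype(self.net.dtype)

        # grouped validation split
        n = x.shape[0]
        if groups is not None:
            uniq = np.unique(np.asarray(groups))
        else:
            uniq = np.array([])
        if uniq.size >= 2:
            n_val = max(1, int(round(cfg.val_fraction * uniq.size)))
            n_val = min(n_val, uniq.size - 1)
            val_groups = rng.permutation(uniq)[:n_val]
            val_mask = np.isin(groups, val_groups)
        else:
            val_mask = np.zeros(n, dtype=bool)
            val_mask[rng.permutation(n)[: max(1, int(cfg.val_fraction * n))]] = True
        train_idx = np.flatnonzero(~val_mask)
        val_idx = np.flatnonzero(val_mask)

        params = self.net.params
        opt = Adam(params, lr=cfg.learning_rate)
        stopper = EarlyStopping(cfg.early_stop_patience_epochs)
        best_params = self.net.get_params()
        train_losses: list[float] = []
        val_losses: list[float] = []
        n_batches = 0
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            n_batches = 0
            for i in range(0, order.size, cfg.batch_size):
                batch = order[i : i + cfg.batch_size]
                loss, grads = self.net.loss_and_grads(xs[batch], y[batch])
                opt.step(params, grads)
                epoch_loss += loss * batch.size
                n_batches += 1
            train_losses.append(epoch_loss / order.size)
            val_probs = self.net.predict_proba(xs[val_idx])
            val_losses.append(soft_cross_entropy(val_probs, y[val_idx]))
            improved = val_losses[-1] == min(val_losses)
            if improved:
                best_params = self.net.get_params()
            if stopper.update(val_losses[-1]):
                break
        self.net.set_params(best_params)
        self.trained = True
        self.training_log = {
            "n_epochs": len(train_losses),
            "best_epoch": stopper.best_epoch,
            "stopped_early": len(train_losses) < self.cfg.max_epochs,
            "train_loss": train_losses,
            "val_loss": val_losses,
            "batch_size": cfg.batch_size,
            "batches_per_epoch": n_batches,
            "n_train_windows": int(train_idx.size),
            "n_val_windows": int(val_idx.size),
        }
        return self.training_log

    # ---- inference ---------------------------------------------------

    def predict_trace(
        self,
        pre: PreprocessedSignals,
        window_s: float = 0.75,
        step_s: float = 0.025,
    ) -> ProbabilityTrace:
        if not self.trained:
            raise StateError("detector has not been trained")
        x, _, centers = make_window_arrays(pre, None, window_s, step_s)
        probs = self.net.predict_proba(
            self._standardize(x).astype(self.net.dtype)
        ).astype(float)
        # guard against float32 round-off in the softmax
        probs /= probs.sum(axis=1, keepdims=True)
        return ProbabilityTrace(centers, probs[:, 0], probs[:, 1])

    # ---- persistence -------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "cfg": self.cfg.__dict__ | {"dense_sizes": list(self.cfg.dense_sizes)},
            "window_len": self.window_len,
            "n_channels": self.n_channels,
            "trained": self.trained,
            "training_log": self.training_log,
        }
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        np.savez(path, meta=json.dumps(meta), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MotionDetector":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = DetectorConfig(**meta["cfg"])
        det = cls(cfg, window_len=meta["window_len"], n_channels=meta["n_channels"])
        det.net.set_params(
            {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        )
        if "norm_mean" in data.files:
            det.norm_mean = data["norm_mean"]
            det.norm_std = data["norm_std"]
        det.trained = bool(meta["trained"])
        det.training_log = meta["training_log"]
        return det


# ---- module-level surface -------------------------------------------


def build_detector(cfg: DetectorConfig, window_len: int = 30) -> MotionDetector:
    return MotionDetector(cfg, window_len=window_len)


def training_windows(
    cohort: list[tuple[ImuRecording, GroundTruthLabel]],
    cfg: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Soft-labelled training windows for a cohort, tagged by subject.

    Training windows advance by ``cfg.detector.train_step_s`` (default
    0.1 s): adjacent windows at the inference step overlap by >95 % and
    add little information, so a coarser training stride keeps the
    training set compact without changing what the network sees.
    """
    xs, ys, gs = [], [], []
    for rec, label in cohort:
        pre = preprocess(rec)
        x, y, _ = make_window_arrays(
            pre, label.interval, cfg.window_s, cfg.detector.train_step_s
        )
        xs.append(x)
        ys.append(y)
        gs.append(np.repeat(rec.subject_id, x.shape[0]))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(gs)


def train_detector(
    detector: MotionDetector,
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict:
    return detector.fit(x, y, groups)


def predict_trace(
    detector: MotionDetector,
    pre: PreprocessedSignals,
    window_s: float = 0.75,
    step_s: float = 0.025,
) -> ProbabilityTrace:
    return detector.predict_trace(pre, window_s, step_s)


def loso_train_predict(
    cohort: list[tuple[ImuRecording, GroundTruthLabel]],
    cfg: PipelineConfig,
    return_audit: bool = False,
):
    """Leave-one-subject-out training: one trace per held-out subject.

    For each subject a fresh detector is trained on every other subject's
    windows and applied to the held-out recording only.  With
    ``return_audit`` the per-fold training-subject lists are returned as
    well, so tests can verify the held-out subject never leaks into its
    own training fold.
    """
    if len(cohort) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    ids = [rec.subject_id for rec, _ in cohort]
    if len(set(ids)) != len(ids):
        raise ValidationError("subject ids must be unique")
    x_all, y_all, g_all = training_windows(cohort, cfg)
    w = int(round(cfg.window_s * cohort[0][0].sampling_rate_hz))
    traces: dict[str, ProbabilityTrace] = {}
    audit: dict[str, list[str]] = {}
    for rec, _label in cohort:
        mask = g_all != rec.subject_id
        det = build_detector(cfg.detector, window_len=w)
        det.fit(x_all[mask], y_all[mask], g_all[mask])
        traces[rec.subject_id] = det.predict_trace(
            preprocess(rec), cfg.window_s, cfg.step_s
        )
        audit[rec.subject_id] = sorted(set(g_all[mask]))
    if return_audit:
        return traces, audit
    return traces
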