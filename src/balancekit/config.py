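"""Pipeline configuration.

All tunable constants of the pipeline live here with their defaults:
window length 0.75 s, step 0.025 s (one sample at 40 Hz), mean-filter
lengths of 1 / 1.25 / 1.5 s, the 0.5 probability and peak-height
thresholds of the interval rules, the 45 % relative peak-height threshold
of the AP peak-count feature, and the 360-degree cumulative-turn limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .types import ValidationError

__all__ = ["DetectorConfig", "ClassifierSpec", "PipelineConfig", "load_config"]

MEAN_FILTER_CHOICES = (1.0, 1.25, 1.5)


@dataclass
class DetectorConfig:
    """Hyperparameters of the conv-LSTM window classifier.

    The convolution (32 filters, kernel 3), batch size 200 and the
    20-epoch early-stopping patience are fixed protocol choices; the LSTM
    width and dense sizes are free and default to the smallest sizes that
    solve the synthetic detection task robustly.  The first two dense
    layers are linear (no activation); the last is a 2-way softmax.
    """

    conv_filters: int = 32
    kernel_size: int = 3
    lstm_units: int = 32
    dense_sizes: tuple[int, ...] = (64, 32, 2)
    batch_size: int = 200
    early_stop_patience_epochs: int = 20
    max_epochs: int = 60
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    train_step_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.dense_sizes = tuple(int(s) for s in self.dense_sizes)
        for name in (
            "conv_filters",
            "kernel_size",
            "lstm_units",
            "batch_size",
            "early_stop_patience_epochs",
            "max_epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if any(s <= 0 for s in self.dense_sizes):
            raise ValidationError("dense sizes must be positive")
        if self.dense_sizes[-1] != 2:
            raise ValidationError("last dense layer must have size 2")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValidationError("val_fraction must lie in (0, 1)")
        if self.train_step_s <= 0:
            raise ValidationError("train_step_s must be positive")


@dataclass
class ClassifierSpec:
    """Choice of subject-level classifier on the scalar balance feature."""

    kind: str = "knn"  # one of {"one_class_svm", "lda", "knn"}
    knn_k: int = 5
    ocsvm_nu: float = 0.1
    ocsvm_gamma: str | float = "scale"
    standardize: bool = True

    KINDS = ("one_class_svm", "lda", "knn")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k <= 0 or self.knn_k % 2 == 0:
            raise ValidationError("knn_k must be odd and positive")
        if not 0.0 < self.ocsvm_nu < 1.0:
            raise ValidationError("ocsvm_nu must lie in (0, 1)")


@dataclass
class PipelineConfig:
    """End-to-end pipeline constants; every stage reads from here."""

    window_s: float = 0.75
    step_s: float = 0.025
    mean_filter_s: float = 1.0
    prob_threshold: float = 0.5
    peak_height_threshold: float = 0.5
    peak_prominence: float = 0.5
    peak_min_separation_s: float = 0.25
    ap_peak_frac: float = 0.45
    turn_limit_deg: float = 360.0
    turn_tolerance: float = 1.05
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.detector, dict):
            self.detector = DetectorConfig(**self.detector)
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierSpec(**self.classifier)
        if self.window_s <= 0 or self.step_s <= 0 or self.mean_filter_s <= 0:
            raise ValidationError("window_s, step_s, mean_filter_s must be positive")
        for name in (
            "prob_threshold",
            "peak_height_threshold",
            "peak_prominence",
            "ap_peak_frac",
        ):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValidationError(f"{name}={value} outside (0, 1]")
        if self.turn_limit_deg <= 0:
            raise ValidationError("turn_limit_deg must be positive")
        if self.turn_tolerance < 1.0:
            raise ValidationError("turn_tolerance must be >= 1")
        if self.peak_min_separation_s < 0:
            raise ValidationError("peak_min_separation_s must be >= 0")

    def window_samples(self, fs: float) -> int:
        w = int(round(self.window_s * fs))
        if w < 1:
            raise ValidationError("window_s shorter than one sample")
        return w

    def step_samples(self, fs: float) -> int:
        return max(1, int(round(self.step_s * fs)))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file.

    Absent keys take the documented defaults; an empty file yields the
    all-defaults configuration.  Unknown keys and out-of-range values raise
    :class:`~balancekit.types.ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw)}")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
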