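"""Subject classification and evaluation.

A subject's single feature value is classified as normal vs
deviating-from-healthy with a one-class SVM (trained on the normal class
only), LDA, or k-NN, evaluated leave-one-subject-out.  Detection quality
is the per-sample agreement between detected and true interval
indicators; classifier quality is pooled LOSO accuracy plus the ROC AUC
(computed by the Mann-Whitney rank formulation, so ties are handled by
rank averaging).  Agreement between the manual-label and detected-label
pipelines uses the McNemar test on discordant pairs,
``z^2 = (n12 - n21)^2 / (n12 + n21)`` against chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import OneClassSVM

from .config import ClassifierSpec
from .types import Condition, MotionInterval, ValidationError

__all__ = [
    "ClassifierSpec",
    "EvalResult",
    "McNemarResult",
    "AgreementReport",
    "fit_predict",
    "loso_assess",
    "detection_accuracy",
    "roc_auc",
    "mcnemar",
    "agreement_report",
]


@dataclass
class EvalResult:
    """Pooled LOSO outcome; `deviating` is the positive class."""

    accuracy: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int
    predictions: dict[str, Condition] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class McNemarResult:
    n12: int
    n21: int
    z2: float
    p_value: float
    degenerate: bool = False  # no discordant pairs at all


@dataclass
class AgreementReport:
    mcnemar: McNemarResult
    mean_feature_diff: float | None = None
    wilcoxon_stat: float | None = None
    wilcoxon_p: float | None = None


def _as_conditions(labels) -> np.ndarray:
    return np.asarray([Condition(l) for l in labels], dtype=object)


def _label_array(deviating_mask: np.ndarray) -> np.ndarray:
    return np.asarray(
        [Condition.DEVIATING if b else Condition.NORMAL for b in deviating_mask],
        dtype=object,
    )


def _is_deviating(labels) -> np.ndarray:
    # identity test per element: numpy's broadcast == mishandles str enums
    return np.fromiter(
        (Condition(l) is Condition.DEVIATING for l in labels), dtype=bool,
        count=len(labels),
    )


def _standardize(train: np.ndarray, test: np.ndarray):
    mu, sd = train.mean(), train.std()
    if sd < 1e-12:
        sd = 1.0
    return (train - mu) / sd, (test - mu) / sd


def fit_predict(
    spec: ClassifierSpec,
    train_features: np.ndarray,
    train_labels,
    test_features: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training fold, predict the test features.

    Returns ``(labels, scores)`` with scores oriented so that larger
    means more deviating: the negated decision function for the one-class
    SVM, the deviating-class posterior for LDA, and the deviating
    neighbour fraction for k-NN.
    """
    x_train = np.asarray(train_features, dtype=float).ravel()
    x_test = np.atleast_1d(np.asarray(test_features, dtype=float)).ravel()
    y_train = _as_conditions(train_labels)
    if x_train.size != y_train.size:
        raise ValidationError("features and labels must align")
    if spec.standardize:
        x_train, x_test = _standardize(x_train, x_test)
    xt = x_train.reshape(-1, 1)
    xq = x_test.reshape(-1, 1)
    deviating = _is_deviating(y_train)

    if spec.kind == "one_class_svm":
        if not (~deviating).any():
            raise ValidationError("one-class SVM needs normal training samples")
        model = OneClassSVM(kernel="rbf", nu=spec.ocsvm_nu, gamma=spec.ocsvm_gamma)
        model.fit(xt[~deviating])
        scores = -model.decision_function(xq)
        # Discrete features put most training mass on one value, which then
        # sits exactly on the learned margin (decision = 0).  Counting the
        # margin as inside keeps the nu upper bound on the training-outlier
        # fraction meaningful; the tolerance absorbs solver round-off.
        labels = _label_array(scores > 1e-6)
    elif spec.kind == "lda":
        if deviating.all() or (~deviating).all():
            raise ValidationError("LDA needs both classes in training")
        model = LinearDiscriminantAnalysis()
        model.fit(xt, [c.value for c in y_train])
        dev_col = list(model.classes_).index(Condition.DEVIATING.value)
        scores = model.predict_proba(xq)[:, dev_col]
        labels = _label_array(scores > 0.5)
    elif spec.kind == "knn":
        if deviating.all() or (~deviating).all():
            raise ValidationError("k-NN needs both classes in training")
        k = min(spec.knn_k, x_train.size)
        scores = np.empty(x_test.size)
        for i, value in enumerate(x_test):
            d = np.abs(x_train - value)
            # stable sort: equal distances resolved by smaller train index
            nearest = np.argsort(d, kind="stable")[:k]
            scores[i] = float(np.mean(deviating[nearest]))
        labels = _label_array(scores > 0.5)
    else:  # pragma: no cover - ClassifierSpec validates kind
        raise ValidationError(f"unknown classifier {spec.kind}")
    return labels, np.asarray(scores, dtype=float)


def loso_assess(
    features_by_subject: dict[str, float],
    labels_by_subject: dict[str, Condition],
    spec: ClassifierSpec,
) -> EvalResult:
    """Leave-one-subject-out evaluation of the feature classifier."""
    subjects = list(features_by_subject)
    if set(subjects) != set(labels_by_subject):
        raise ValidationError("feature and label subject sets differ")
    if len(subjects) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    values = np.array([features_by_subject[s] for s in subjects], dtype=float)
    truth = _as_conditions([labels_by_subject[s] for s in subjects])
    if _is_deviating(truth).all() or not _is_deviating(truth).any():
        raise ValidationError("cohort must contain both classes")
    preds: dict[str, Condition] = {}
    scores: dict[str, float] = {}
    for i, sid in enumerate(subjects):
        mask = np.ones(len(subjects), dtype=bool)
        mask[i] = False
        label, score = fit_predict(spec, values[mask], truth[mask], values[i])
        preds[sid] = Condition(label[0])
        scores[sid] = float(score[0])
    pos = _is_deviating(truth)
    hat = _is_deviating([preds[s] for s in subjects])
    tp = int((pos & hat).sum())
    tn = int((~pos & ~hat).sum())
    fp = int((~pos & hat).sum())
    fn = int((pos & ~hat).sum())
    auc = roc_auc(np.array([scores[s] for s in subjects]), pos)
    return EvalResult(
        accuracy=(tp + tn) / len(subjects),
        auc=auc,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        predictions=preds,
        scores=scores,
    )


def detection_accuracy(
    detected: MotionInterval,
    truth: MotionInterval,
    duration_s: float,
    fs: float = 40.0,
) -> float:
    """Per-sample agreement of the two interval indicators over [0, duration]."""
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    det = (t >= detected.start_s - 1e-12) & (t <= detected.end_s + 1e-12)
    tru = (t >= truth.start_s - 1e-12) & (t <= truth.end_s + 1e-12)
    return float(np.mean(det == tru))


def roc_auc(scores: np.ndarray, labels) -> float:
    """Area under the empirical ROC via the Mann-Whitney statistic.

    Equivalent to the probability that a random positive outscores a
    random negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype == object:
        labels = _is_deviating(labels)
    labels = labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mcnemar(n12: int, n21: int) -> McNemarResult:
    """McNemar agreement test from the discordant-pair counts."""
    if n12 < 0 or n21 < 0:
        raise ValidationError("discordant counts must be >= 0")
    total = n12 + n21
    if total == 0:
        return McNemarResult(0, 0, z2=0.0, p_value=1.0, degenerate=True)
    z2 = (n12 - n21) ** 2 / total
    return McNemarResult(
        int(n12), int(n21), z2=float(z2), p_value=float(stats.chi2.sf(z2, df=1))
    )


def agreement_report(
    manual_predictions: dict[str, Condition],
    detected_predictions: dict[str, Condition],
    manual_features: dict[str, float] | None = None,
    detected_features: dict[str, float] | None = None,
) -> AgreementReport:
    """Agreement between manual-interval and detected-interval pipelines.

    ``n12`` counts subjects the manual pipeline calls deviating but the
    detected pipeline calls normal; ``n21`` the reverse.  When paired
    feature values are supplied the report adds their mean difference and
    a Wilcoxon signed-rank test.
    """
    if set(manual_predictions) != set(detected_predictions):
        raise ValidationError("prediction subject sets differ")
    subjects = sorted(manual_predictions)
    man = _is_deviating([manual_predictions[s] for s in subjects])
    det = _is_deviating([detected_predictions[s] for s in subjects])
    n12 = int((man & ~det).sum())
    n21 = int((~man & det).sum())
    report = AgreementReport(mcnemar=mcnemar(n12, n21))
    if manual_features is not None and detected_features is not None:
        if set(manual_features) != set(detected_features):
            raise ValidationError("feature subject sets differ")
        diffs = np.array(
            [manual_features[s] - detected_features[s] for s in sorted(manual_features)]
        )
        report.mean_feature_diff = float(diffs.mean())
        if np.any(diffs != 0):
            stat, p = stats.wilcoxon(diffs)
            report.wilcoxon_stat = float(stat)
            report.wilcoxon_p = float(p)
        else:
            report.wilcoxon_stat = 0.0
            report.wilcoxon_p = 1.0
    return report
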