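"""Forecast evaluation: ROC/AUC with Hanley-McNeil confidence intervals,
sensitivity / time-in-high operating points, and multi-class confusion
matrices against a time-matched random baseline.

Conventions: the positive class is pre-ictal (label 0); sensitivity is
sample-level (every pre-ictal minute must be classified pre-ictal, stricter
than per-seizure event scoring); time in high is the fraction of all
predictions flagged pre-ictal.  Two AUCs differ significantly when their
confidence intervals do not overlap; an AUC beats chance when the lower
bound of its interval exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocCurve",
    "AucWithCi",
    "OperatingPoint",
    "ConfusionReport",
    "combine_scores",
    "roc_auc",
    "hanley_mcneil_ci",
    "compare_aucs",
    "vs_random",
    "operating_points",
    "match_point",
    "confusion_and_baseline",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class AucWithCi:
    auc: float
    half_width: float
    n_pos: int
    n_neg: int
    level: float = 0.95

    @property
    def lower(self) -> float:
        return self.auc - self.half_width

    @property
    def upper(self) -> float:
        return self.auc + self.half_width

    def __str__(self) -> str:  # Table-style "0.86 (+/-0.039)"
        return f"{self.auc:.2f} (+/-{self.half_width:.3f})"


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    time_in_high: float


def combine_scores(outputs: np.ndarray) -> np.ndarray:
    """Single receiver-operator score from the two model outputs.

    score = pre_score - inter_score with fixed weights (+1, -1); any
    strictly monotone linear combination induces the same ROC ordering,
    so the weights are not tuned.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[1] != 2:
        raise ValueError(
            f"combine_scores is for two-label outputs, got {outputs.shape[1]}; "
            "use confusion_and_baseline for multi-class runs"
        )
    return outputs[:, 0] - outputs[:, 1]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC by threshold sweep and AUC by trapezoidal integration.

    ``labels`` is 1 for pre-ictal (positive).  Tied scores contribute at a
    single threshold, which makes the trapezoidal AUC equal to the
    Mann-Whitney statistic with tie midpoints.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both classes (n_pos={n_pos}, n_neg={n_neg})")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> AucWithCi:
    """Closed-form AUC confidence interval (Hanley & McNeil 1982).

    SE^2 = [A(1-A) + (n_pos - 1)(Q1 - A^2) + (n_neg - 1)(Q2 - A^2)]
           / (n_pos * n_neg),   Q1 = A / (2 - A),  Q2 = 2 A^2 / (1 + A).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need n_pos >= 1 and n_neg >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se2 = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    z = float(norm.ppf(0.5 + level / 2.0))
    return AucWithCi(
        auc=a,
        half_width=z * float(np.sqrt(max(se2, 0.0))),
        n_pos=n_pos,
        n_neg=n_neg,
        level=level,
    )


def compare_aucs(a: AucWithCi, b: AucWithCi) -> bool:
    """True when the difference is significant: the intervals do not overlap."""
    return a.upper < b.lower or b.upper < a.lower


def vs_random(a: AucWithCi) -> bool:
    """True when the AUC beats a random predictor: lower CI bound above 0.5."""
    return a.lower > 0.5


def operating_points(scores: np.ndarray, labels: np.ndarray) -> list[OperatingPoint]:
    """Sensitivity and time-in-high at every distinct threshold.

    A sample is flagged pre-ictal when score >= threshold; sensitivity is
    the flagged fraction of pre-ictal samples, time in high the flagged
    fraction of all samples.  Both are monotone non-increasing in the
    threshold.  Sentinel endpoints (all flagged / none flagged) included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    n_pos = int((labels == 1).sum())
    uniq = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    out = []
    for thr in thresholds:
        flagged = scores >= thr
        sens = float(flagged[labels == 1].sum() / n_pos) if n_pos else 0.0
        tih = float(flagged.sum() / n) if n else 0.0
        out.append(OperatingPoint(float(thr), sens, tih))
    return out


def match_point(
    scores: np.ndarray,
    labels: np.ndarray,
    target_sensitivity: float | None = None,
    target_time_in_high: float | None = None,
) -> OperatingPoint:
    """Operating point closest to a target sensitivity or time in high.

    Exactly one target must be given; ties in closeness resolve toward the
    lower time in high (less time spent in warning).
    """
    if (target_sensitivity is None) == (target_time_in_high is None):
        raise ValueError("give exactly one of the two targets")
    points = operating_points(scores, labels)
    if target_sensitivity is not None:
        key = lambda p: (abs(p.sensitivity - target_sensitivity), p.time_in_high)
    else:
        key = lambda p: (abs(p.time_in_high - target_time_in_high), p.time_in_high)
    return min(points, key=key)


@dataclass
class ConfusionReport:
    """Multi-class counts with the time-matched random-baseline comparison.

    ``baseline_sensitivity[k]`` is the sensitivity a random predictor would
    reach for label k if it selected label k as often as the model does
    (the model's selection proportion).  ``better`` / ``better_by_margin``
    flag labels where the model's row-normalized sensitivity beats that
    baseline (at all / by more than 0.1).
    """

    counts: np.ndarray
    row_normalized: np.ndarray
    total_accuracy: float
    selection_proportions: np.ndarray
    baseline_sensitivity: np.ndarray
    model_sensitivity: np.ndarray
    better: np.ndarray
    better_by_margin: np.ndarray


def confusion_and_baseline(
    y_true: np.ndarray, y_pred: np.ndarray, n_labels: int, margin: float = 0.1
) -> ConfusionReport:
    """Confusion matrix (rows = actual) plus the random-baseline report."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_labels)).astype(float)
    n = counts.sum()
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_norm = np.where(row_sums > 0, counts / row_sums, 0.0)
    selection = counts.sum(axis=0) / n if n else np.zeros(n_labels)
    model_sens = np.diag(row_norm)
    baseline = selection.copy()
    return ConfusionReport(
        counts=counts,
        row_normalized=row_norm,
        total_accuracy=float(np.trace(counts) / n) if n else 0.0,
        selection_proportions=selection,
        baseline_sensitivity=baseline,
        model_sensitivity=model_sens,
        better=model_sens > baseline,
        better_by_margin=model_sens > baseline + margin,
    )
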