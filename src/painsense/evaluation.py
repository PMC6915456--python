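"""Regression and classification metrics for pain-score estimation.

Regression quality is reported as RMSE (same 0-10 units as the pain
score) and the Pearson correlation between predicted and actual scores;
the natural baseline is the mean-only model, whose RMSE equals the
population standard deviation of the scores.

For the ordinal 4-level comparison, scores are categorized as none (0),
mild (1-3), moderate (4-6) and severe (7-10); fractional scores use the
half-open bins [0,1), [1,4), [4,7), [7,10] anchored at those integer
bounds.  Classification is summarised by accuracy, per-class F1 and the
support-weighted F1, the appropriate summary for the severely imbalanced
class counts seen in an acute-pain clinic.  A continuous regressor is
compared against the classifier by clamping its predictions into [0, 10]
and categorizing them the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .types import PainCategory, ValidationError

__all__ = [
    "rmse",
    "pearson_r",
    "categorize",
    "categorize_scores",
    "weighted_f1",
    "ClassificationResult",
    "classification_report",
    "regression_as_classifier",
    "residual_table",
]


def _paired(actual, predicted) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.ndim != 1 or p.ndim != 1 or a.shape != p.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValidationError("empty input")
    return a, p


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error, in pain-score units."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def pearson_r(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Product-moment correlation in [-1, 1]; undefined when either input
    has zero variance."""
    a, p = _paired(actual, predicted)
    if a.size < 2:
        raise ValidationError("pearson_r requires at least 2 samples")
    if np.std(a) == 0.0 or np.std(p) == 0.0:
        raise ValidationError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(a, p).statistic)


_BIN_EDGES = np.array([1.0, 4.0, 7.0])  # none < 1 <= mild < 4 <= moderate < 7 <= severe


def categorize(score: float) -> PainCategory:
    """Map a 0-10 score onto the ordinal 4-level pain scale."""
    if not (0.0 <= score <= 10.0):
        raise ValidationError(f"score {score} outside [0, 10]")
    return PainCategory(int(np.searchsorted(_BIN_EDGES, score, side="right")))


def categorize_scores(scores: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`categorize`; returns an int array of levels."""
    arr = np.asarray(scores, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 10.0):
        raise ValidationError("scores outside [0, 10]")
    return np.searchsorted(_BIN_EDGES, arr, side="right")


def weighted_f1(f1_per_class: Sequence[float], support: Sequence[int]) -> float:
    """Support-weighted mean of per-class F1 scores.

    Zero-support classes contribute nothing to numerator or denominator.
    """
    f1 = np.asarray(f1_per_class, dtype=float)
    sup = np.asarray(support, dtype=float)
    if f1.shape != sup.shape:
        raise ValidationError("f1_per_class and support lengths differ")
    if np.sum(sup) <= 0:
        raise ValidationError("total support must be positive")
    return float(np.sum(f1 * sup) / np.sum(sup))


@dataclass
class ClassificationResult:
    """4-level classification summary.

    Per-class maps only contain classes with support > 0 (absent classes
    are reported as absent, not as F1 = 0).
    """

    accuracy: float
    f1_per_class: Dict[PainCategory, float]
    precision_per_class: Dict[PainCategory, float]
    recall_per_class: Dict[PainCategory, float]
    support: Dict[PainCategory, int]
    weighted_f1: float


def classification_report(
    actual_cat: Sequence[int], predicted_cat: Sequence[int]
) -> ClassificationResult:
    """Accuracy, per-class precision/recall/F1 and support-weighted F1.

    F1 is 0 when precision + recall is 0.  The weighted F1 averages over
    classes actually present in the data, weighted by their counts.
    """
    a = np.asarray([int(PainCategory(int(c))) for c in actual_cat])
    p = np.asarray([int(PainCategory(int(c))) for c in predicted_cat])
    if a.shape != p.shape:
        raise ValidationError("length mismatch")
    if a.size == 0:
        raise ValidationError("empty input")
    labels = sorted(set(a.tolist()))  # classes with support > 0
    prec, rec, f1, sup = precision_recall_fscore_support(
        a, p, labels=labels, zero_division=0
    )
    return ClassificationResult(
        accuracy=float(np.mean(a == p)),
        f1_per_class={PainCategory(l): float(v) for l, v in zip(labels, f1)},
        precision_per_class={PainCategory(l): float(v) for l, v in zip(labels, prec)},
        recall_per_class={PainCategory(l): float(v) for l, v in zip(labels, rec)},
        support={PainCategory(l): int(s) for l, s in zip(labels, sup)},
        weighted_f1=weighted_f1(f1, sup),
    )


def regression_as_classifier(
    actual_scores: Sequence[float], predicted_scores: Sequence[float]
) -> ClassificationResult:
    """Evaluate a continuous regressor on the 4-level scale.

    Predictions are clamped into [0, 10], then both vectors are
    categorized and scored like a classifier — the apples-to-apples
    comparison between SVR and SVM.
    """
    a, p = _paired(actual_scores, predicted_scores)
    return classification_report(
        categorize_scores(a), categorize_scores(np.clip(p, 0.0, 10.0))
    )


def residual_table(
    actual: Sequence[float], predicted: Sequence[float]
) -> Tuple[pd.DataFrame, float]:
    """Per-sample residuals (actual - predicted) plus the ± band value,
    the population standard deviation of the actual scores (the mean-only
    baseline RMSE), for residual-versus-predicted plots."""
    a, p = _paired(actual, predicted)
    df = pd.DataFrame({"predicted": p, "actual": a, "residual": a - p})
    return df, float(np.std(a))
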