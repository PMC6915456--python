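"""End-to-end orchestration: sessions -> matched records -> feature table
-> cross-validated models and metrics.

These helpers glue the stage modules together for the CLI and for
experiment scripts; each stage remains usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import MatchConfig, match_session
from .evaluation import (
    ClassificationResult,
    categorize_scores,
    classification_report,
    pearson_r,
    regression_as_classifier,
    rmse,
)
from .features import FilterConfig, extract_features
from .io import FeatureEntry, feature_table_frame
from .modeling import CVConfig, ModelSpec, cv_predict
from .types import SessionBundle, ValidationError

logger = logging.getLogger("painsense")

__all__ = [
    "build_feature_entries",
    "build_feature_table",
    "split_feature_table",
    "evaluate_regression",
    "evaluate_classification",
    "RegressionEval",
]

META_COLUMNS = ("session_id", "t_min", "score", "source")


def build_feature_entries(
    bundles: Iterable[SessionBundle],
    match_cfg: MatchConfig = MatchConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
) -> Tuple[List[FeatureEntry], int]:
    """Match and featurize every session; returns the feature entries plus
    the count of pain reports left unmatched."""
    entries: List[FeatureEntry] = []
    n_unmatched = 0
    for bundle in bundles:
        matched, unmatched = match_session(bundle, match_cfg)
        n_unmatched += len(unmatched)
        for rec in matched:
            fv = extract_features(rec.segment, filter_cfg)
            entries.append((bundle.session_id, rec.pain, fv))
    return entries, n_unmatched


def build_feature_table(
    bundles: Iterable[SessionBundle],
    match_cfg: MatchConfig = MatchConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Wide feature table (one row per matched record) for a cohort."""
    entries, n_unmatched = build_feature_entries(bundles, match_cfg, filter_cfg)
    if n_unmatched:
        logger.info("dropped %d unmatched pain report(s)", n_unmatched)
    return feature_table_frame(entries)


def split_feature_table(
    df: pd.DataFrame,
) -> Tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Split a feature table into (X, y, meta), dropping (and logging)
    rows with flagged-missing feature values."""
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    complete = df[feature_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing feature values", n_dropped)
    kept = df[complete]
    X = kept[feature_cols].reset_index(drop=True)
    y = kept["score"].to_numpy(dtype=float)
    meta = kept[list(META_COLUMNS)].reset_index(drop=True)
    return X, y, meta


@dataclass
class RegressionEval:
    """Out-of-fold regression evaluation for one model family."""

    family: str
    rmse: float
    pearson_r: float
    baseline_sd: float  # mean-only baseline RMSE = population sd of scores
    predictions: np.ndarray = field(repr=False)
    actual: np.ndarray = field(repr=False)


def evaluate_regression(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    cv: CVConfig = CVConfig(),
    selected: Optional[Sequence[str]] = None,
) -> RegressionEval:
    """10-fold (by default) out-of-fold RMSE and Pearson r for one family."""
    if spec.is_classifier:
        raise ValidationError("evaluate_regression expects a regression family")
    cols = list(selected) if selected is not None else list(X.columns)
    preds = cv_predict(spec, X[cols], y, cv)
    return RegressionEval(
        family=spec.family,
        rmse=rmse(y, preds),
        pearson_r=pearson_r(y, preds),
        baseline_sd=float(np.std(y)),
        predictions=preds,
        actual=np.asarray(y, dtype=float),
    )


def evaluate_classification(
    spec: ModelSpec,
    X: pd.DataFrame,
    y_scores: np.ndarray,
    cv: CVConfig = CVConfig(),
    selected: Optional[Sequence[str]] = None,
) -> ClassificationResult:
    """Out-of-fold 4-level evaluation.

    For the svm family the targets are categorized before training and the
    predicted levels are scored directly; for a regression family the
    continuous out-of-fold predictions are clamped and categorized
    (regression-as-classifier), so both routes share fold structure.
    """
    cols = list(selected) if selected is not None else list(X.columns)
    if spec.is_classifier:
        y_cat = categorize_scores(y_scores)
        preds = cv_predict(spec, X[cols], y_cat, cv)
        return classification_report(y_cat, np.rint(preds).astype(int))
    preds = cv_predict(spec, X[cols], y_scores, cv)
    return regression_as_classifier(y_scores, preds)
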