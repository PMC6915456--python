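"""Cross-validated regression/classification and greedy wrapper selection.

Model families mirror the four regressors used for pain-score estimation —
ridge, lasso, Gaussian-process regression (GPR) and support-vector
regression (SVR) — plus a support-vector classifier (SVM) for the 4-level
pain scale.  Kernel methods use an RBF kernel whose scale is set on each
training fold by the median-distance heuristic, so the SVR and SVM kernels
are identical when the two are compared.

Feature selection is the wrapper method: greedy forward selection /
backward elimination scored by the cross-validated RMSE of the chosen
model family, since the wrapper is defined relative to a given learning
algorithm.  Cross-validation pools rows from all sessions (between-subject
modelling); per-fold standardization prevents test-fold leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from .types import ValidationError

__all__ = [
    "ModelSpec",
    "CVConfig",
    "SelectionResult",
    "FittedModel",
    "cv_predict",
    "wrapper_select",
    "fit_final",
    "median_heuristic_length_scale",
]

REGRESSION_FAMILIES = ("ridge", "lasso", "gpr", "svr")
ALL_FAMILIES = REGRESSION_FAMILIES + ("svm",)

_DEFAULT_HYPERPARAMS: Dict[str, Dict[str, float]] = {
    "ridge": {"alpha": 1.0},
    "lasso": {"alpha": 1.0},
    "gpr": {"alpha": 0.1},  # observation-noise nugget on normalized targets
    "svr": {"C": 1.0, "epsilon": 0.1},
    "svm": {"C": 1.0},
}


@dataclass(frozen=True)
class ModelSpec:
    """One model family with fixed (not nested-tuned) hyperparameters."""

    family: str
    kernel: str = "rbf"
    hyperparams: Dict[str, float] = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}; expected one of {ALL_FAMILIES}")
        if self.family in ("gpr", "svr", "svm") and self.kernel != "rbf":
            raise ValidationError("only the rbf kernel is supported for gpr/svr/svm")
        merged = dict(_DEFAULT_HYPERPARAMS[self.family])
        merged.update(self.hyperparams)
        object.__setattr__(self, "hyperparams", merged)

    @property
    def is_classifier(self) -> bool:
        return self.family == "svm"


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation setup (default 10-fold, shuffled)."""

    k: int = 10
    shuffle_seed: int = 0
    stratify: bool = False
    group_by_session: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be at least 2")


def median_heuristic_length_scale(X: np.ndarray) -> float:
    """RBF length scale = median pairwise Euclidean distance (on the
    standardized training fold); falls back to sqrt(n_features) when the
    median degenerates to zero."""
    if X.shape[0] < 2 or X.shape[1] == 0:
        return 1.0
    d = pdist(X)
    med = float(np.median(d))
    if med <= 0.0:
        return float(np.sqrt(max(1, X.shape[1])))
    return med


class _Scaler:
    """Per-fold feature standardization (train-fold statistics only)."""

    def __init__(self, X: np.ndarray, enabled: bool):
        if enabled and X.shape[1]:
            self.mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0.0] = 1.0
            self.sd = sd
        else:
            self.mean = np.zeros(X.shape[1])
            self.sd = np.ones(X.shape[1])

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _build_estimator(spec: ModelSpec, X_train: np.ndarray):
    hp = spec.hyperparams
    if spec.family == "ridge":
        return Ridge(alpha=hp["alpha"])
    if spec.family == "lasso":
        return Lasso(alpha=hp["alpha"], max_iter=10000)
    ls = median_heuristic_length_scale(X_train)
    if spec.family == "gpr":
        return GaussianProcessRegressor(
            kernel=RBF(length_scale=ls),
            alpha=hp["alpha"],
            optimizer=None,
            normalize_y=True,
        )
    gamma = 1.0 / (2.0 * ls * ls)
    if spec.family == "svr":
        return SVR(kernel="rbf", gamma=gamma, C=hp["C"], epsilon=hp["epsilon"])
    return SVC(kernel="rbf", gamma=gamma, C=hp["C"])


class _ConstantModel:
    """Mean-only (or majority-class) fallback: empty feature set or a
    constant-target training fold."""

    def __init__(self, y: np.ndarray, classifier: bool):
        if classifier:
            vals, counts = np.unique(y, return_counts=True)
            self.value = vals[np.argmax(counts)]
        else:
            self.value = float(np.mean(y))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.value)


def _as_matrix(X: Union[pd.DataFrame, np.ndarray]) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        mat = X.to_numpy(dtype=float)
        cols = list(X.columns)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat.reshape(-1, 1)
        cols = [f"x{i}" for i in range(mat.shape[1])]
    if np.isnan(mat).any():
        raise ValidationError(
            "feature matrix contains missing values; drop flagged-missing rows upstream"
        )
    return mat, cols


def _fit_one(spec: ModelSpec, X_train: np.ndarray, y_train: np.ndarray):
    """Fit scaler + estimator on one training fold; returns (scaler, model)."""
    scaler = _Scaler(X_train, spec.standardize)
    Xs = scaler(X_train)
    if Xs.shape[1] == 0:
        return scaler, _ConstantModel(y_train, spec.is_classifier)
    if np.unique(y_train).size < 2:
        warnings.warn("constant-target training fold; fitting intercept only", stacklevel=3)
        return scaler, _ConstantModel(y_train, spec.is_classifier)
    model = _build_estimator(spec, Xs)
    model.fit(Xs, y_train)
    return scaler, model


def cv_predict(
    spec: ModelSpec,
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    cv: CVConfig = CVConfig(),
    groups: Optional[Sequence] = None,
) -> np.ndarray:
    """Out-of-fold predictions: every sample is predicted by a model that
    never saw it, with standardization and kernel scale fit on the
    training folds only.  Deterministic given ``cv.shuffle_seed``."""
    mat, _ = _as_matrix(X)
    y_arr = np.asarray(y)
    n = mat.shape[0]
    if y_arr.shape[0] != n:
        raise ValidationError("X and y lengths differ")
    if n < cv.k:
        raise ValidationError(f"n_samples={n} is smaller than k={cv.k} folds")

    if cv.group_by_session:
        if groups is None:
            raise ValidationError("group_by_session requires a groups vector")
        splitter = GroupKFold(n_splits=cv.k)
        splits = splitter.split(mat, y_arr, groups=np.asarray(groups))
    elif cv.stratify and spec.is_classifier:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.shuffle_seed)
        splits = splitter.split(mat, y_arr)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.shuffle_seed)
        splits = splitter.split(mat)

    preds = np.empty(n, dtype=float)
    for train_idx, test_idx in splits:
        scaler, model = _fit_one(spec, mat[train_idx], y_arr[train_idx])
        preds[test_idx] = model.predict(scaler(mat[test_idx]))
    return preds


def _cv_rmse(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    cols: Sequence[str],
    cv: CVConfig,
) -> float:
    preds = cv_predict(spec, X[list(cols)], y, cv)
    return float(np.sqrt(np.mean((np.asarray(y, dtype=float) - preds) ** 2)))


@dataclass
class SelectionResult:
    """Outcome of one greedy wrapper run.

    ``selected`` is in add order for forward selection and original column
    order for backward elimination; ``trajectory`` records every candidate
    subset evaluated with its CV RMSE; ``objective`` is the final CV RMSE
    of the selected set.
    """

    direction: str
    selected: List[str]
    trajectory: List[Tuple[Tuple[str, ...], float]]
    objective: float
    objective_name: str = "rmse"
    steps: List[Tuple[str, str, float]] = field(default_factory=list)  # (action, feature, objective)


def wrapper_select(
    direction: str,
    spec: ModelSpec,
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    cv: CVConfig = CVConfig(),
    tol: float = 1e-4,
    max_features: Optional[int] = None,
) -> SelectionResult:
    """Greedy wrapper feature selection scored by CV RMSE.

    forward: start from the empty (mean-only) model and repeatedly add the
    feature that most lowers CV RMSE, stopping once the best improvement
    is <= tol.  backward: start from the full set and repeatedly drop the
    feature whose removal most improves (or least harms) CV RMSE, stopping
    once the best removal worsens it by > tol.  Candidate ties break
    lexicographically by feature name.  ``max_features`` (forward only)
    stops the search early once that many features are selected.
    """
    if direction not in ("forward", "backward"):
        raise ValidationError("direction must be 'forward' or 'backward'")
    if spec.is_classifier:
        raise ValidationError("wrapper selection uses a regression objective; got svm")
    mat, cols = _as_matrix(X)
    if not cols:
        raise ValidationError("wrapper_select requires at least one feature")
    frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(mat, columns=cols)
    y_arr = np.asarray(y, dtype=float)
    trajectory: List[Tuple[Tuple[str, ...], float]] = []
    steps: List[Tuple[str, str, float]] = []

    def objective(subset: Sequence[str]) -> float:
        val = _cv_rmse(spec, frame, y_arr, subset, cv)
        trajectory.append((tuple(subset), val))
        return val

    if direction == "forward":
        current: List[str] = []
        current_obj = objective(current)  # mean-only baseline
        remaining = sorted(cols)
        while remaining and (max_features is None or len(current) < max_features):
            best_feat, best_obj = None, None
            for f in remaining:  # lexicographic order; strict < keeps first tie
                obj = objective(current + [f])
                if best_obj is None or obj < best_obj:
                    best_feat, best_obj = f, obj
            if current_obj - best_obj > tol:
                current.append(best_feat)
                remaining.remove(best_feat)
                current_obj = best_obj
                steps.append(("add", best_feat, best_obj))
            else:
                break
        selected = current
    else:
        current = list(cols)
        current_obj = objective(current)
        while current:
            best_feat, best_obj = None, None
            for f in sorted(current):
                subset = [c for c in current if c != f]
                obj = objective(subset)
                if best_obj is None or obj < best_obj:
                    best_feat, best_obj = f, obj
            if best_obj - current_obj <= tol:
                current.remove(best_feat)
                current_obj = best_obj
                steps.append(("remove", best_feat, best_obj))
            else:
                break
        selected = current

    return SelectionResult(
        direction=direction,
        selected=selected,
        trajectory=trajectory,
        objective=current_obj,
        steps=steps,
    )


@dataclass
class FittedModel:
    """Opaque fitted-model handle restricted to the selected features."""

    spec: ModelSpec
    selected: List[str]
    _scaler: _Scaler
    _model: object

    def predict(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.selected if c not in X.columns]
            if missing:
                raise ValidationError(f"prediction input lacks selected feature(s): {missing}")
            mat = X[self.selected].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat.reshape(-1, 1)
            if mat.shape[1] != len(self.selected):
                raise ValidationError(
                    f"expected {len(self.selected)} feature columns, got {mat.shape[1]}"
                )
        return self._model.predict(self._scaler(mat))


def fit_final(
    spec: ModelSpec,
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    selected: Sequence[str],
) -> FittedModel:
    """Fit one model on all rows, restricted to the selected features."""
    if not selected:
        raise ValidationError("selected feature list must be non-empty")
    mat, cols = _as_matrix(X)
    frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(mat, columns=cols)
    missing = [c for c in selected if c not in frame.columns]
    if missing:
        raise ValidationError(f"unknown selected feature(s): {missing}")
    sub = frame[list(selected)].to_numpy(dtype=float)
    scaler, model = _fit_one(spec, sub, np.asarray(y))
    return FittedModel(spec=spec, selected=list(selected), _scaler=scaler, _model=model)
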