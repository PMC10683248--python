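"""Algorithm selection by nested cross-validation and the final logistic scorer.

Six candidate families (AdaBoost, decision tree, random forest, logistic
regression, k-neighbours, SVM) are compared by nested CV: an inner 5-fold
grid search tunes hyperparameters on each outer-training fold, the refit
model is scored on the outer held-out fold (outer cv = 10 by default), and
folds are stratified by label. Imputation and normalization are part of the
cross-validated pipeline, so their parameters are refit inside every fold
and never see held-out rows.

The production model is a logistic regression: Pr = sigmoid(b + sum_i w_i x_i)
on imputed, min-max-normalized features. |w_i| serves as feature importance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (
    FeatureMatrix,
    ImputerState,
    NormalizerState,
    fit_impute,
    fit_normalize,
    transform_impute,
    transform_normalize,
)

ALGORITHM_NAMES = (
    "adaboost",
    "decision_tree",
    "random_forest",
    "logistic_regression",
    "kneighbors",
    "svm",
)

# Deterministic convex solver for the logistic family: lbfgs with the
# documented convergence tolerance and iteration cap.
LR_TOL = 1e-6
LR_MAX_ITER = 1000

# SVC probabilities are required for pooled AUC across outer folds; the
# sklearn 1.9 deprecation of the flag is tolerated until the replacement
# (CalibratedClassifierCV) is adopted.
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)


class TrainingError(ValueError):
    pass


def _make_estimator(name: str, seed: int | None = 0, **params):
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "logistic_regression":
        # L2 regularization is the solver default; L1 available via params
        defaults = dict(C=1.0, solver="lbfgs", tol=LR_TOL, max_iter=LR_MAX_ITER)
        defaults.update(params)
        return LogisticRegression(**defaults)
    if name == "kneighbors":
        return KNeighborsClassifier(**params)
    if name == "svm":
        return SVC(probability=True, random_state=seed, **params)
    raise TrainingError(
        f"unknown algorithm {name!r}; expected one of {ALGORITHM_NAMES}"
    )


def default_grids() -> dict[str, dict[str, list]]:
    """Compact documented hyperparameter grids for the six families."""
    return {
        "adaboost": {"n_estimators": [50, 100]},
        "decision_tree": {"max_depth": [3, 5, None]},
        "random_forest": {"n_estimators": [100], "max_depth": [None, 5]},
        "logistic_regression": {"C": [0.1, 1.0, 10.0]},
        "kneighbors": {"n_neighbors": [5, 11]},
        "svm": {"kernel": ["rbf", "linear"], "C": [1.0]},
    }


@dataclass(frozen=True)
class CandidateAlgorithm:
    name: str
    hyperparameter_grid: Mapping[str, list]

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise TrainingError(f"unknown algorithm {self.name!r}")
        if not self.hyperparameter_grid or any(
            len(v) == 0 for v in self.hyperparameter_grid.values()
        ):
            raise TrainingError(f"{self.name}: hyperparameter grid must be non-empty")


def default_candidates() -> list[CandidateAlgorithm]:
    return [CandidateAlgorithm(n, g) for n, g in default_grids().items()]


class KnnImputeStep(BaseEstimator, TransformerMixin):
    """sklearn adapter over the package's KNN imputer (fold-local state)."""

    def __init__(self, k: int = 5, feature_names: tuple[str, ...] = ()):
        self.k = k
        self.feature_names = feature_names

    def _wrap(self, X: np.ndarray) -> FeatureMatrix:
        names = self.feature_names or tuple(f"f{j}" for j in range(X.shape[1]))
        return FeatureMatrix([str(i) for i in range(len(X))], names, X)

    def fit(self, X, y=None):
        self.state_, _ = fit_impute(self._wrap(np.asarray(X, float)), k=self.k)
        return self

    def transform(self, X):
        return transform_impute(self.state_, self._wrap(np.asarray(X, float))).values


class MinMaxStep(BaseEstimator, TransformerMixin):
    """sklearn adapter over the package's min-max normalizer."""

    def __init__(self, feature_names: tuple[str, ...] = ()):
        self.feature_names = feature_names

    def _wrap(self, X: np.ndarray) -> FeatureMatrix:
        names = self.feature_names or tuple(f"f{j}" for j in range(X.shape[1]))
        return FeatureMatrix([str(i) for i in range(len(X))], names, X)

    def fit(self, X, y=None):
        self.state_, _ = fit_normalize(self._wrap(np.asarray(X, float)))
        return self

    def transform(self, X):
        return transform_normalize(self.state_, self._wrap(np.asarray(X, float))).values


def _make_pipeline(name: str, seed: int, impute_k: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", KnnImputeStep(k=impute_k)),
            ("scale", MinMaxStep()),
            ("clf", _make_estimator(name, seed=seed)),
        ]
    )


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CandidateResult:
    name: str
    best_params_per_fold: list[dict]
    fold_accuracies: list[float]
    accuracy: float  # %, pooled out-of-fold predictions
    precision: float  # %
    auc: float
    f1: float
    recall: float  # %
    mcc: float

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(
            self.fold_accuracies
        ) > 1 else 0.0


@dataclass
class FoldStates:
    """Fold-local preprocessing state, kept for leakage diagnostics."""

    imputer: ImputerState
    normalizer: NormalizerState


@dataclass
class CVReport:
    candidates: dict[str, CandidateResult]
    outer_k: int
    inner_k: int
    seed: int
    fold_states: dict[str, list[FoldStates]] = field(default_factory=dict)

    def best_candidate(self) -> str:
        return max(self.candidates.values(), key=lambda c: c.auc).name

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.candidates.values():
            rows.append(
                {
                    "method": c.name,
                    "accuracy_pct": round(c.accuracy, 2),
                    "precision_pct": round(c.precision, 2),
                    "auc": round(c.auc, 3),
                    "f1": round(c.f1, 3),
                    "recall_pct": round(c.recall, 2),
                    "mcc": round(c.mcc, 3),
                    "outer_mean_accuracy": round(c.mean_accuracy, 3),
                    "outer_sd_accuracy": round(c.sd_accuracy, 3),
                }
            )
        return pd.DataFrame(rows)


def _check_stratifiable(y: np.ndarray, outer_k: int, inner_k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("both classes must be present")
    if counts.min() < outer_k:
        raise TrainingError(
            f"minority class has {counts.min()} rows; cannot stratify "
            f"{outer_k} outer folds"
        )
    # worst-case inner training share of the minority class
    inner_min = counts.min() * (outer_k - 1) // outer_k
    if inner_min < inner_k:
        raise TrainingError(
            f"minority class too small for {inner_k} inner folds "
            f"inside {outer_k} outer folds"
        )


def nested_cv_select(
    matrix: FeatureMatrix,
    candidates: Sequence[CandidateAlgorithm] | None = None,
    inner_k: int = 5,
    outer_k: int = 10,
    seed: int = 0,
    impute_k: int = 5,
    collect_states: bool = False,
) -> CVReport:
    """Select among candidate algorithm families by nested stratified CV.

    For each candidate and each outer fold, an inner ``inner_k``-fold grid
    search (accuracy-scored) picks hyperparameters on the outer-training
    rows; the refit pipeline — imputer and normalizer included — is then
    scored on the outer held-out fold. Table-2-style metrics are computed on
    the pooled out-of-fold predictions; per-fold accuracies are reported
    alongside their mean and standard deviation.
    """
    if matrix.labels is None:
        raise TrainingError("labels required for cross-validation")
    if candidates is None:
        candidates = default_candidates()
    X, y = matrix.values, matrix.labels
    _check_stratifiable(y, outer_k, inner_k)
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    report = CVReport(candidates={}, outer_k=outer_k, inner_k=inner_k, seed=seed)
    splits = list(outer.split(X, y))
    for cand in candidates:
        oof_pred = np.empty(len(y), dtype=int)
        oof_score = np.empty(len(y), dtype=float)
        fold_acc: list[float] = []
        best_params: list[dict] = []
        states: list[FoldStates] = []
        for train_idx, test_idx in splits:
            pipe = _make_pipeline(cand.name, seed, impute_k)
            grid = {f"clf__{k}": v for k, v in cand.hyperparameter_grid.items()}
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + 1)
            search = GridSearchCV(pipe, grid, cv=inner, scoring="accuracy", refit=True)
            search.fit(X[train_idx], y[train_idx])
            best = search.best_estimator_
            pred = best.predict(X[test_idx])
            proba = best.predict_proba(X[test_idx])[:, 1]
            oof_pred[test_idx] = pred
            oof_score[test_idx] = proba
            fold_acc.append(float((pred == y[test_idx]).mean()))
            best_params.append(
                {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
            )
            if collect_states:
                states.append(
                    FoldStates(
                        imputer=best.named_steps["impute"].state_,
                        normalizer=best.named_steps["scale"].state_,
                    )
                )
        tp = int(((oof_pred == 1) & (y == 1)).sum())
        fp = int(((oof_pred == 1) & (y == 0)).sum())
        fn = int(((oof_pred == 0) & (y == 1)).sum())
        precision = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
        recall = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall) / 100.0
            if precision + recall
            else 0.0
        )
        report.candidates[cand.name] = CandidateResult(
            name=cand.name,
            best_params_per_fold=best_params,
            fold_accuracies=fold_acc,
            accuracy=100.0 * float((oof_pred == y).mean()),
            precision=precision,
            auc=float(roc_auc_score(y, oof_score)),
            f1=float(f1),
            recall=recall,
            mcc=float(matthews_corrcoef(y, oof_pred)),
        )
        if collect_states:
            report.fold_states[cand.name] = states
    return report


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainedModel:
    """Fitted scorer with its frozen preprocessing state.

    For the logistic family the stored coefficients define the score
    directly (Pr = sigmoid(intercept + w . x_normalized)); other families
    keep their fitted estimator in memory and cannot be JSON-persisted.
    """

    algorithm: str
    feature_names: tuple[str, ...]
    coefficients: np.ndarray | None
    intercept: float | None
    imputer: ImputerState
    normalizer: NormalizerState
    default_threshold: float = 0.5
    seed: int = 0
    estimator: object | None = None  # non-LR families only

    def save(self, path) -> None:
        if self.algorithm != "logistic_regression":
            raise TrainingError(
                "JSON persistence is defined for logistic_regression only"
            )
        payload = {
            "format": "mmis-model-v1",
            "algorithm": self.algorithm,
            "feature_names": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "imputer": self.imputer.to_json(),
            "normalizer": self.normalizer.to_json(),
            "default_threshold": self.default_threshold,
            "seed": self.seed,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            algorithm=payload["algorithm"],
            feature_names=tuple(payload["feature_names"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            imputer=ImputerState.from_json(payload["imputer"]),
            normalizer=NormalizerState.from_json(payload["normalizer"]),
            default_threshold=payload.get("default_threshold", 0.5),
            seed=payload.get("seed", 0),
        )


def fit_final(
    matrix: FeatureMatrix,
    algorithm: str = "logistic_regression",
    hyperparameters: Mapping | None = None,
    impute_k: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Fit imputer, normalizer and classifier on the entire training matrix."""
    if matrix.labels is None:
        raise TrainingError("labels required to fit the final model")
    if len(np.unique(matrix.labels)) < 2:
        raise TrainingError("both classes must be present in the training labels")
    imputer, completed = fit_impute(matrix, k=impute_k)
    normalizer, scaled = fit_normalize(completed)
    est = _make_estimator(algorithm, seed=seed, **(hyperparameters or {}))
    est.fit(scaled.values, matrix.labels)
    if algorithm == "logistic_regression":
        coef = np.asarray(est.coef_[0], dtype=float)
        intercept = float(est.intercept_[0])
    else:
        coef, intercept = None, None
    return TrainedModel(
        algorithm=algorithm,
        feature_names=matrix.feature_names,
        coefficients=coef,
        intercept=intercept,
        imputer=imputer,
        normalizer=normalizer,
        seed=seed,
        estimator=est,
    )


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Per-row pathogenicity probability Pr in [0,1].

    Columns are aligned by name (permutation-safe); missing columns or
    extras raise an error listing the differences.
    """
    if set(matrix.feature_names) != set(model.feature_names):
        missing = sorted(set(model.feature_names) - set(matrix.feature_names))
        extra = sorted(set(matrix.feature_names) - set(model.feature_names))
        raise TrainingError(
            f"feature mismatch: missing {missing}, unexpected {extra}"
        )
    aligned = matrix.select_columns(model.feature_names)
    completed = transform_impute(model.imputer, aligned)
    scaled = transform_normalize(model.normalizer, completed)
    if model.algorithm == "logistic_regression":
        z = model.intercept + scaled.values @ model.coefficients
        return _sigmoid(z)
    if model.estimator is None:
        raise TrainingError("non-logistic model has no in-memory estimator")
    return model.estimator.predict_proba(scaled.values)[:, 1]


def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Features ranked by |w_i| descending; ties broken alphabetically."""
    if model.algorithm != "logistic_regression":
        raise TrainingError(
            "feature importance via |w_i| is defined for logistic_regression only"
        )
    pairs = [
        (name, abs(float(w)))
        for name, w in zip(model.feature_names, model.coefficients)
    ]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def denormalized_coefficients(model: TrainedModel) -> tuple[np.ndarray, float]:
    """Coefficients on the original (pre-min-max) feature scale.

    With u_j = (x_j - min_j)/scale_j the fitted score is
    b + sum_j w_j u_j = (b - sum_j w_j min_j / scale_j) + sum_j (w_j/scale_j) x_j.
    """
    if model.algorithm != "logistic_regression":
        raise TrainingError("defined for logistic_regression only")
    w = model.coefficients / model.normalizer.scales
    b = model.intercept - float(
        np.sum(model.coefficients * model.normalizer.mins / model.normalizer.scales)
    )
    return w, b


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveResult:
    training_sizes: list[int]
    train_mean: list[float]
    train_sd: list[float]
    validation_mean: list[float]
    validation_sd: list[float]


def learning_curve(
    matrix: FeatureMatrix,
    algorithm: str = "logistic_regression",
    sizes: Sequence[int] = (),
    cv_k: int = 5,
    seed: int = 0,
    impute_k: int = 5,
    hyperparameters: Mapping | None = None,
) -> LearningCurveResult:
    """Train/validation accuracy as a function of training-set size.

    For each size a stratified subsample of each CV fold's training rows is
    fitted and scored on the subsample and on the fold's validation rows.
    Sizes must be strictly increasing and at least twice the class count.
    """
    if matrix.labels is None:
        raise TrainingError("labels required for a learning curve")
    sizes = list(sizes)
    if not sizes:
        raise TrainingError("at least one training size required")
    if len(set(sizes)) != len(sizes):
        raise TrainingError("duplicate training sizes rejected")
    if sizes != sorted(sizes):
        raise TrainingError("training sizes must be strictly increasing")
    n_classes = len(np.unique(matrix.labels))
    if min(sizes) < 2 * n_classes:
        raise TrainingError(
            f"smallest size {min(sizes)} < 2 x {n_classes} classes"
        )
    X, y = matrix.values, matrix.labels
    skf = StratifiedKFold(n_splits=cv_k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    max_train = min(len(tr) for tr, _ in splits)
    if max(sizes) > max_train:
        raise TrainingError(
            f"largest size {max(sizes)} exceeds available training rows "
            f"({max_train}) after the CV split"
        )
    rng = np.random.default_rng(seed)
    tr_means, tr_sds, va_means, va_sds = [], [], [], []
    for size in sizes:
        tr_scores, va_scores = [], []
        for train_idx, test_idx in splits:
            sub = _stratified_subsample(y[train_idx], size, rng)
            idx = train_idx[sub]
            pipe = _make_pipeline(algorithm, seed, impute_k)
            if hyperparameters:
                pipe.named_steps["clf"].set_params(**hyperparameters)
            pipe.fit(X[idx], y[idx])
            tr_scores.append(float((pipe.predict(X[idx]) == y[idx]).mean()))
            va_scores.append(
                float((pipe.predict(X[test_idx]) == y[test_idx]).mean())
            )
        tr_means.append(float(np.mean(tr_scores)))
        tr_sds.append(float(np.std(tr_scores, ddof=1)) if cv_k > 1 else 0.0)
        va_means.append(float(np.mean(va_scores)))
        va_sds.append(float(np.std(va_scores, ddof=1)) if cv_k > 1 else 0.0)
    return LearningCurveResult(sizes, tr_means, tr_sds, va_means, va_sds)


def _stratified_subsample(y: np.ndarray, size: int, rng) -> np.ndarray:
    """Indices of a label-stratified subsample of ``size`` rows."""
    classes, counts = np.unique(y, return_counts=True)
    take = np.maximum(1, np.round(size * counts / len(y)).astype(int))
    # adjust rounding drift while keeping each class non-empty
    while take.sum() > size:
        take[int(np.argmax(take))] -= 1
    while take.sum() < size:
        take[int(np.argmin(take / counts))] += 1
    chosen = []
    for cls, t in zip(classes, take):
        idx = np.flatnonzero(y == cls)
        chosen.append(rng.choice(idx, size=min(t, len(idx)), replace=False))
    return np.sort(np.concatenate(chosen))
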