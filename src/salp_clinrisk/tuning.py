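"""Search spaces, cross-validated fitness, SSA tuning, and the baseline zoo.

The swarm tunes random forest (four integer hyperparameters) and XGBoost
(five hyperparameters, two continuous) over the published search boundaries,
minimizing 1 minus the mean stratified K-fold cross-validated accuracy on
the training partition. SMOTE is applied inside each fold to the fold-train
part only, so the fold-validation rows never leak into the oversampling
neighbour pool. The baseline zoo fits eight classifier families at library
defaults for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import ssa
from .preprocess import smote_oversample

__all__ = [
    "FAMILIES",
    "TUNABLE_FAMILIES",
    "ModelSpec",
    "FitnessResult",
    "rf_search_space",
    "xgb_search_space",
    "default_assignment",
    "build_model",
    "cv_fitness",
    "tune",
    "baseline_zoo",
]

FAMILIES = (
    "random_forest",
    "xgboost",
    "logistic_regression",
    "svm",
    "knn",
    "decision_tree",
    "mlp",
    "gaussian_nb",
)
TUNABLE_FAMILIES = ("random_forest", "xgboost")


def rf_search_space() -> ssa.SearchSpace:
    """Published random-forest search box: four integer dimensions."""
    return ssa.SearchSpace(
        [
            ssa.Dimension("n_estimators", 50, 500, "integer"),
            ssa.Dimension("max_depth", 3, 30, "integer"),
            ssa.Dimension("min_samples_split", 2, 20, "integer"),
            ssa.Dimension("min_samples_leaf", 1, 10, "integer"),
        ]
    )


def xgb_search_space() -> ssa.SearchSpace:
    """Published XGBoost search box: three integer + two continuous dims."""
    return ssa.SearchSpace(
        [
            ssa.Dimension("n_estimators", 50, 500, "integer"),
            ssa.Dimension("max_depth", 3, 15, "integer"),
            ssa.Dimension("learning_rate", 0.01, 0.3, "continuous"),
            ssa.Dimension("gamma", 0.0, 1.0, "continuous"),
            ssa.Dimension("min_child_weight", 1, 10, "integer"),
        ]
    )


def search_space(family: str) -> ssa.SearchSpace:
    if family == "random_forest":
        return rf_search_space()
    if family == "xgboost":
        return xgb_search_space()
    raise ValueError(f"no search space for family {family!r}")


def default_assignment(family: str) -> dict[str, float | int]:
    """Library-default hyperparameters clipped into the search box.

    Used as the optional warm-start leader position; sklearn's unbounded
    defaults (max_depth=None) map to the box's upper bound.
    """
    if family == "random_forest":
        return {"n_estimators": 100, "max_depth": 30, "min_samples_split": 2,
                "min_samples_leaf": 1}
    if family == "xgboost":
        return {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.3,
                "gamma": 0.0, "min_child_weight": 1}
    raise ValueError(f"no default assignment for family {family!r}")


def build_model(family: str, params: dict | None = None, seed: int = 0):
    """Instantiate one classifier family with probability outputs.

    Non-searched hyperparameters stay at library defaults; SVM gets
    Platt-calibrated probabilities (``probability=True``).
    """
    params = dict(params or {})
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "xgboost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **params
        )
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(max_iter=1000, random_state=seed, **params)
    if family == "gaussian_nb":
        return GaussianNB(**params)
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A fitted model plus the provenance needed to re-fit it."""

    family: str
    hyperparameters: dict
    seed: int
    estimator: object = field(compare=False, repr=False)

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


@dataclass(frozen=True)
class FitnessResult:
    fold_accuracies: tuple[float, ...]

    @property
    def fitness(self) -> float:
        return 1.0 - float(np.mean(self.fold_accuracies))


def cv_fitness(
    assignment: dict,
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    smote_in_folds: bool = True,
    smote_k: int = 5,
    binary_columns: np.ndarray | None = None,
) -> FitnessResult:
    """Stratified K-fold classification-error fitness for one assignment.

    Within each fold the model is fitted on the (optionally SMOTE-balanced)
    fold-train rows and scored by plain accuracy at threshold 0.5 on the
    untouched fold-validation rows; the fitness is 1 - mean fold accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold} has a single class in its training part")
        X_fit, y_fit = X[tr], y_tr
        if smote_in_folds:
            X_fit, y_fit = smote_oversample(
                X_fit, y_fit, k_neighbors=smote_k, seed=seed + fold,
                binary_columns=binary_columns,
            )
        model = build_model(family, assignment, seed=seed)
        model.fit(X_fit, y_fit)
        accuracies.append(float(np.mean(model.predict(X[va]) == y[va])))
    return FitnessResult(fold_accuracies=tuple(accuracies))


def tune(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    n_salps: int = 20,
    n_iterations: int = 50,
    seed: int = 0,
    cv_k: int = 5,
    warm_start: bool = False,
    smote_in_folds: bool = True,
    smote_k: int = 5,
    binary_columns: np.ndarray | None = None,
    fit_final: bool = True,
    X_final: np.ndarray | None = None,
    y_final: np.ndarray | None = None,
) -> tuple[ModelSpec, ssa.OptimizationResult]:
    """SSA-tune one family's hyperparameters on the training partition.

    ``warm_start`` seeds the leader at the library-default assignment, so by
    elitism the tuned cross-validation fitness can never exceed the default
    model's fitness on the same folds. The returned estimator is fitted on
    ``(X_final, y_final)`` when given (the pipeline passes the
    SMOTE-augmented full training partition), else on ``(X, y)``.
    """
    if family not in TUNABLE_FAMILIES:
        raise ValueError(f"family {family!r} is not SSA-tunable")
    space = search_space(family)

    def fitness(position: np.ndarray) -> float:
        assignment = ssa.decode_position(position, space)
        return cv_fitness(
            assignment, family, X, y, k=cv_k, seed=seed,
            smote_in_folds=smote_in_folds, smote_k=smote_k,
            binary_columns=binary_columns,
        ).fitness

    x0 = None
    if warm_start:
        defaults = default_assignment(family)
        x0 = np.array([defaults[d.name] for d in space.dimensions], dtype=float)

    result = ssa.optimize(
        fitness, space, n_salps=n_salps, n_iterations=n_iterations, seed=seed, x0=x0
    )
    estimator = build_model(family, result.best_assignment, seed=seed)
    if fit_final:
        if X_final is None:
            X_final, y_final = X, y
        estimator.fit(np.asarray(X_final, dtype=float), np.asarray(y_final))
    spec = ModelSpec(
        family=family,
        hyperparameters=dict(result.best_assignment),
        seed=seed,
        estimator=estimator,
    )
    return spec, result


def baseline_zoo(X: np.ndarray, y: np.ndarray, seed: int = 0,
                 families: tuple[str, ...] = FAMILIES) -> list[ModelSpec]:
    """Fit every baseline family at library defaults with a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    specs = []
    for family in families:
        model = build_model(family, seed=seed)
        model.fit(X, y)
        specs.append(ModelSpec(family=family, hyperparameters={}, seed=seed, estimator=model))
    return specs
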