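"""Classifier training under repeated stratified cross-validation.

Six classifier families are screened for epitope/non-epitope
discrimination: support vector machine (SVM), random forest (RF),
extremely randomized trees (ERT), gradient boosting (GB), AdaBoost (AB)
and k-nearest neighbours (KNN).  All expose a probability for the
positive class; threshold metrics inside cross-validation use the 0.5
cutoff (decision cutoffs are optimized later, see :mod:`.ensemble`).

The evaluation protocol is stratified 5-fold cross-validation repeated
10 times with fresh random partitions.  Within each repeat a grid search
picks the hyperparameter combination maximizing mean held-out MCC across
the five folds; the final reported hyperparameters are the per-parameter
median (mode for categoricals) of the per-repeat winners, and aggregate
performance is the mean over all folds and repeats.

Hyperparameter grids are compact, documented defaults sized for
single-workstation runs and can be overridden per
:class:`ClassifierConfig`.  All randomness derives from one master seed
through named substreams (fold assignment per repeat, model seeding), so
a rerun with the same seed reproduces the report bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from statistics import mode
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import MetricsReport, confusion, metrics, roc_auc
from .features import FeatureMatrix, FeatureSpec

ALGORITHMS = ("SVM", "RF", "ERT", "GB", "AB", "KNN")

#: Compact default hyperparameter search spaces, per algorithm.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [0.1, 1.0, 10.0]},
    "RF": {"n_estimators": [100, 200]},
    "ERT": {"n_estimators": [100, 200]},
    "GB": {"n_estimators": [100], "learning_rate": [0.05, 0.1]},
    "AB": {"n_estimators": [50, 100]},
    "KNN": {"n_neighbors": [5, 15]},
}


@dataclass(frozen=True)
class ClassifierConfig:
    """An algorithm, its hyperparameter grid, and a master seed."""

    algorithm: str
    grid: Optional[dict[str, list]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.grid is not None and not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def effective_grid(self) -> dict[str, list]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]


@dataclass
class TrainedClassifier:
    """A fitted model plus the feature spec and decision cutoff it carries."""

    algorithm: str
    model: object
    hyperparameters: dict
    spec: Optional[FeatureSpec] = None
    cutoff: float = 0.5

    def predict_proba(self, X: np.ndarray | FeatureMatrix) -> np.ndarray:
        """Positive-class probabilities for encoded rows."""
        if isinstance(X, FeatureMatrix):
            X = X.values
        proba = self.model.predict_proba(X)
        pos_col = int(np.where(self.model.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def predict_probabilities(self, peptides: Sequence) -> np.ndarray:
        """Encode peptides under this classifier's spec and score them."""
        from .features import encode

        if self.spec is None:
            raise ValueError("classifier carries no feature spec")
        return self.predict_proba(encode(peptides, self.spec).values)


@dataclass
class CVReport:
    """Repeated cross-validation results for one algorithm/feature pair."""

    algorithm: str
    folds: int
    repeats: int
    #: per repeat, per fold threshold metrics (0.5 cutoff) with fold AUC
    fold_metrics: list[list[MetricsReport]]
    #: winning hyperparameters of each repeat's grid search
    chosen_params: list[dict]
    #: per-parameter median (mode for categoricals) over repeats
    median_params: dict
    #: mean over all folds and repeats of each metric
    aggregate: dict[str, float]
    #: (repeats, n_samples) out-of-fold positive-class probabilities
    oof_probabilities: np.ndarray
    seed: int


def make_estimator(algorithm: str, params: dict, seed: int):
    """Instantiate a scikit-learn estimator for one algorithm family.

    Distance/margin-based learners (SVM, KNN) get feature
    standardization in a pipeline; tree ensembles are scale-invariant
    and run on raw descriptors.
    """
    if algorithm == "SVM":
        est = SVC(probability=True, random_state=seed, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if algorithm == "KNN":
        est = KNeighborsClassifier(**params)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "ERT":
        return ExtraTreesClassifier(random_state=seed, **params)
    if algorithm == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "AB":
        return AdaBoostClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, pos_col]


def _grid_combinations(grid: dict[str, list]) -> list[dict]:
    names = list(grid)
    return [dict(zip(names, combo)) for combo in product(*(grid[n] for n in names))]


def _median_params(chosen: list[dict]) -> dict:
    out = {}
    for name in chosen[0]:
        values = [c[name] for c in chosen]
        if all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in values):
            med = float(np.median(values))
            if all(isinstance(v, int) for v in values):
                med = int(round(med))
            out[name] = med
        else:
            out[name] = mode(values)
    return out


def cross_validate(
    X: np.ndarray | FeatureMatrix,
    y: Sequence[int],
    config: ClassifierConfig,
    folds: int = 5,
    repeats: int = 10,
) -> CVReport:
    """Repeated stratified k-fold CV with per-repeat grid search on MCC.

    Every fold's metrics are computed on held-out samples only; the
    out-of-fold probabilities of each repeat's winning hyperparameters
    are kept for downstream cutoff optimization.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    yy = np.asarray(y, dtype=int)
    if X.shape[0] != yy.size:
        raise ValueError("X and y differ in length")
    classes, counts = np.unique(yy, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if folds > counts.min():
        raise ValueError(
            f"folds ({folds}) exceeds the minority class size ({counts.min()})"
        )
    rng = np.random.default_rng(config.seed)
    fold_seeds = rng.integers(2**31, size=repeats)
    model_seed = int(rng.integers(2**31))
    combos = _grid_combinations(config.effective_grid)

    fold_metrics: list[list[MetricsReport]] = []
    chosen_params: list[dict] = []
    oof = np.empty((repeats, yy.size))
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(fold_seeds[r] % 2**31)
        )
        splits = list(skf.split(X, yy))
        best = None  # (mean_mcc, per-fold metrics, oof vector, params)
        for params in combos:
            per_fold = []
            oof_combo = np.empty(yy.size)
            for train_idx, test_idx in splits:
                est = make_estimator(config.algorithm, params, model_seed)
                est.fit(X[train_idx], yy[train_idx])
                prob = _positive_proba(est, X[test_idx])
                oof_combo[test_idx] = prob
                rep = metrics(confusion(prob, yy[test_idx], 0.5), cutoff=0.5)
                _, auc = roc_auc(prob, yy[test_idx])
                per_fold.append(
                    MetricsReport(
                        rep.sensitivity,
                        rep.specificity,
                        rep.accuracy,
                        rep.mcc,
                        auc=auc,
                        cutoff=0.5,
                    )
                )
            mean_mcc = float(np.mean([m.mcc for m in per_fold]))
            if best is None or mean_mcc > best[0]:
                best = (mean_mcc, per_fold, oof_combo, params)
        _, per_fold, oof_vec, params = best
        fold_metrics.append(per_fold)
        chosen_params.append(params)
        oof[r] = oof_vec

    flat = [m for per_repeat in fold_metrics for m in per_repeat]
    aggregate = {
        "sensitivity": float(np.mean([m.sensitivity for m in flat])),
        "specificity": float(np.mean([m.specificity for m in flat])),
        "accuracy": float(np.mean([m.accuracy for m in flat])),
        "mcc": float(np.mean([m.mcc for m in flat])),
        "auc": float(np.mean([m.auc for m in flat])),
    }
    return CVReport(
        algorithm=config.algorithm,
        folds=folds,
        repeats=repeats,
        fold_metrics=fold_metrics,
        chosen_params=chosen_params,
        median_params=_median_params(chosen_params),
        aggregate=aggregate,
        oof_probabilities=oof,
        seed=config.seed,
    )


def fit_final(
    X: np.ndarray | FeatureMatrix,
    y: Sequence[int],
    config: ClassifierConfig,
    hyperparameters: dict,
    spec: Optional[FeatureSpec] = None,
) -> TrainedClassifier:
    """Fit on all rows with the given hyperparameters (cutoff starts at 0.5)."""
    if isinstance(X, FeatureMatrix):
        spec = spec or X.spec
        X = X.values
    X = np.asarray(X, dtype=float)
    yy = np.asarray(y, dtype=int)
    if len(np.unique(yy)) < 2:
        raise ValueError("both classes must be present")
    model_seed = int(np.random.default_rng(config.seed).integers(2**31))
    est = make_estimator(config.algorithm, hyperparameters, model_seed)
    est.fit(X, yy)
    return TrainedClassifier(
        algorithm=config.algorithm,
        model=est,
        hyperparameters=dict(hyperparameters),
        spec=spec,
        cutoff=0.5,
    )
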