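"""Probability-averaging ensembles with an MCC-optimized decision cutoff.

The shipped configuration, EM1, fuses two independently trained
classifiers: extremely randomized trees on AAC+PCP descriptors (hybrid
H7) and gradient boosting on DPC+PCP descriptors (hybrid H15).  The
ensemble probability for a peptide is the unweighted arithmetic mean of
the member probabilities,

    EM = (1/n) * sum_i P_i ,

and a peptide is called an epitope when EM >= cutoff.  The cutoff is
chosen by grid search (step 0.01) maximizing the Matthews correlation
coefficient on pooled out-of-fold probabilities from repeated
cross-validation — out-of-fold rather than training-set scores, to keep
the cutoff free of resubstitution optimism.  Ties go to the smallest
cutoff.

Other member combinations (e.g. adding RF, SVM, AB or KNN) are
constructible through the same API; EM1 is the default because fusing
the two strongest tree ensembles transfers best between benchmark and
independent data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np

from .evaluation import roc_auc
from .features import encode, get_spec
from .models import (
    ClassifierConfig,
    CVReport,
    TrainedClassifier,
    cross_validate,
    fit_final,
)
from .seqio import Peptide

#: EM1: (algorithm, feature spec) pairs fused in the default ensemble.
DEFAULT_MEMBERS: tuple[tuple[str, str], ...] = (("ERT", "H7"), ("GB", "H15"))


@dataclass
class EnsembleModel:
    """Member classifiers fused by probability averaging."""

    members: list[TrainedClassifier]
    cutoff: float = 0.5
    name: str = "EM1"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")

    def predict_probabilities(self, peptides: Sequence[Peptide]) -> np.ndarray:
        """Mean member probability for each peptide (input order)."""
        probs = np.vstack(
            [m.predict_probabilities(peptides) for m in self.members]
        )
        return probs.mean(axis=0)


def ensemble_probability(peptide: Peptide, model: EnsembleModel) -> float:
    """Average member probability for a single peptide."""
    return float(model.predict_probabilities([peptide])[0])


def optimize_cutoff(
    probabilities: Sequence[float],
    y: Sequence[int],
    grid_step: float = 0.01,
) -> tuple[float, float]:
    """Grid search the decision cutoff maximizing MCC.

    Cutoffs ``grid_step, 2*grid_step, ..., 1 - grid_step`` are evaluated
    under the ``probability >= cutoff`` call rule; returns
    ``(cutoff, mcc)`` with ties broken toward the smallest cutoff.
    """
    p = np.asarray(probabilities, dtype=float)
    yy = np.asarray(y, dtype=int)
    if len(np.unique(yy)) < 2:
        raise ValueError("both classes must be present")
    if not (0.0 < grid_step < 1.0):
        raise ValueError("grid_step must lie in (0, 1)")
    n_steps = int(round(1.0 / grid_step)) - 1
    grid = np.round(np.arange(1, n_steps + 1) * grid_step, 10)
    if p.min() == p.max():
        warnings.warn("constant probabilities; cutoff optimization is degenerate")
    pos = yy == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    # vectorized MCC over the whole grid
    calls = p[np.newaxis, :] >= grid[:, np.newaxis]
    tp = (calls & pos).sum(axis=1).astype(float)
    fp = (calls & ~pos).sum(axis=1).astype(float)
    fn = n_pos - tp
    tn = n_neg - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom), 0.0)
    best = int(np.argmax(mcc))  # argmax takes the first (smallest) maximizer
    return float(grid[best]), float(mcc[best])


@dataclass
class EnsembleBuildReport:
    """Cross-validation account of an ensemble build."""

    member_reports: dict[str, CVReport]
    member_cutoffs: dict[str, float]
    member_mcc: dict[str, float]
    member_auc: dict[str, float]
    ensemble_cutoff: float
    ensemble_mcc: float
    ensemble_auc: float
    seed: int
    folds: int
    repeats: int


def build_ensemble(
    benchmark: Sequence[Peptide],
    seed: int,
    members: Sequence[tuple[str, str]] = DEFAULT_MEMBERS,
    folds: int = 5,
    repeats: int = 10,
    grids: Optional[dict[str, dict]] = None,
    name: str = "EM1",
) -> tuple[EnsembleModel, EnsembleBuildReport]:
    """Train member classifiers and fuse them into an ensemble.

    Each member is trained on the labeled benchmark peptides under its
    own feature spec via repeated cross-validation (median
    hyperparameters, then a refit on all data).  Because every member
    receives the same master seed, fold partitions coincide across
    members, so per-repeat out-of-fold member probabilities can be
    averaged sample-wise into out-of-fold ensemble probabilities; the
    ensemble cutoff is optimized on those, pooled over repeats.

    Returns the fitted :class:`EnsembleModel` and a build report with
    member and ensemble cross-validated performance.
    """
    y = np.array([p.label for p in benchmark])
    if any(lbl is None for lbl in y):
        raise ValueError("benchmark peptides must all be labeled")
    y = y.astype(int)

    fitted: list[TrainedClassifier] = []
    reports: dict[str, CVReport] = {}
    cutoffs: dict[str, float] = {}
    mccs: dict[str, float] = {}
    aucs: dict[str, float] = {}
    member_oof: list[np.ndarray] = []
    pooled_y = np.tile(y, repeats)
    for algorithm, spec_name in members:
        key = f"{algorithm}-{spec_name}"
        spec = get_spec(spec_name)
        X = encode(benchmark, spec)
        grid = None if grids is None else grids.get(algorithm)
        config = ClassifierConfig(algorithm=algorithm, grid=grid, seed=seed)
        report = cross_validate(X, y, config, folds=folds, repeats=repeats)
        clf = fit_final(X, y, config, report.median_params, spec=spec)
        pooled = report.oof_probabilities.ravel()
        clf.cutoff, mccs[key] = optimize_cutoff(pooled, pooled_y)
        cutoffs[key] = clf.cutoff
        _, aucs[key] = roc_auc(pooled, pooled_y)
        fitted.append(clf)
        reports[key] = report
        member_oof.append(report.oof_probabilities)

    ensemble_oof = np.mean(member_oof, axis=0)  # (repeats, n)
    pooled = ensemble_oof.ravel()
    ens_cutoff, ens_mcc = optimize_cutoff(pooled, pooled_y)
    _, ens_auc = roc_auc(pooled, pooled_y)

    model = EnsembleModel(members=fitted, cutoff=ens_cutoff, name=name)
    report = EnsembleBuildReport(
        member_reports=reports,
        member_cutoffs=cutoffs,
        member_mcc=mccs,
        member_auc=aucs,
        ensemble_cutoff=ens_cutoff,
        ensemble_mcc=ens_mcc,
        ensemble_auc=ens_auc,
        seed=seed,
        folds=folds,
        repeats=repeats,
    )
    return model, report


def save_model(model, path: str | Path) -> None:
    """Serialize a trained (ensemble or single) classifier with joblib."""
    joblib.dump(model, path)


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`."""
    return joblib.load(path)
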