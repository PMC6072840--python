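"""Performance metrics and significance tests for binary classifiers.

Positive calls follow the ``probability >= cutoff`` rule throughout the
package.  Metrics are the standard confusion-matrix summaries —
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and the
Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention MCC = 0 when any factor of the denominator is zero
(the formula is otherwise undefined there).  AUC is the area under the
ROC curve, equal to the Mann-Whitney probability that a random positive
outscores a random negative (ties count one half).

Classifier pairs are compared with McNemar's test on discordant
correct/incorrect calls, using the continuity-corrected chi-square
statistic and an exact two-sided binomial p-value when discordant pairs
are few.  Compositional contrasts use Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix cell counts for one set of binary calls."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics (Sn/Sp/Acc/MCC) plus optional AUC and the cutoff."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: Optional[float] = None
    cutoff: Optional[float] = None


def confusion(
    probabilities: Sequence[float], y: Sequence[int], cutoff: float
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for the ``probability >= cutoff`` rule."""
    p = np.asarray(probabilities, dtype=float)
    yy = np.asarray(y, dtype=int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != yy.shape:
        raise ValueError("probabilities and labels differ in length")
    calls = p >= cutoff
    pos = yy == 1
    return ConfusionCounts(
        tp=int(np.count_nonzero(calls & pos)),
        tn=int(np.count_nonzero(~calls & ~pos)),
        fp=int(np.count_nonzero(calls & ~pos)),
        fn=int(np.count_nonzero(~calls & pos)),
    )


def metrics(c: ConfusionCounts, cutoff: Optional[float] = None) -> MetricsReport:
    """Sn/Sp/Acc/MCC from confusion counts (AUC is threshold-free; see
    :func:`roc_auc`)."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    tp, tn, fp, fn = (float(x) for x in (c.tp, c.tn, c.fp, c.fn))
    sn = tp / (tp + fn) if tp + fn > 0 else float("nan")
    sp = tn / (tn + fp) if tn + fp > 0 else float("nan")
    acc = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(sn, sp, acc, mcc, auc=None, cutoff=cutoff)


def roc_auc(
    probabilities: Sequence[float], y: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC curve points and AUC.

    Returns ``(points, auc)`` where ``points`` is an (n, 2) array of
    (false positive rate, true positive rate) pairs over all distinct
    score thresholds.  AUC uses the rank-sum (Mann-Whitney) equivalence,
    so tied scores contribute one half.
    """
    p = np.asarray(probabilities, dtype=float)
    yy = np.asarray(y, dtype=int)
    if len(np.unique(yy)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(yy, p)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(yy, p))


def mcnemar(
    preds_a: Sequence[int],
    preds_b: Sequence[int],
    y: Sequence[int],
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """McNemar's test on discordant correct/incorrect calls.

    ``b`` counts samples A got right and B got wrong, ``c`` the reverse.
    Returns the continuity-corrected chi-square statistic
    ``(|b-c|-1)^2 / (b+c)`` with its 1-df p-value; when ``b + c <
    exact_threshold`` the p-value instead comes from the exact two-sided
    binomial test of ``b`` successes in ``b+c`` trials at rate one half.
    ``b + c = 0`` (no discordant pairs) returns p = 1 with a warning.
    """
    a = np.asarray(preds_a, dtype=int)
    bb = np.asarray(preds_b, dtype=int)
    yy = np.asarray(y, dtype=int)
    if not (a.shape == bb.shape == yy.shape):
        raise ValueError("prediction vectors and labels must align")
    correct_a = a == yy
    correct_b = bb == yy
    b = int(np.count_nonzero(correct_a & ~correct_b))
    c = int(np.count_nonzero(~correct_a & correct_b))
    if b + c == 0:
        warnings.warn("no discordant pairs; McNemar test is degenerate")
        return 0.0, 1.0
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    if b + c < exact_threshold:
        p = stats.binomtest(b, b + c, 0.5).pvalue
    else:
        p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), float(p)


def welch_t(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided), positive t when
    ``group1`` has the larger mean."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
        raise ValueError("degenerate: both groups constant with unequal means")
    t, p = stats.ttest_ind(g1, g2, equal_var=False)
    return float(t), float(p)
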