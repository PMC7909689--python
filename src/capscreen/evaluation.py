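"""Classification metrics at a probability threshold, ROC/AUC, and the
statistical comparisons applied to correct vs. incorrect classifications.

AUC is the concordance probability — the chance a random positive outscores
a random negative, ties counted half — which equals the trapezoidal area
under the ROC curve.  A prediction is positive when its probability is
greater than or equal to the threshold (default 0.5).  Ratios with a zero
denominator are reported as NaN and flagged in ``MetricsReport.undefined``,
never silently as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.stats
from sklearn.metrics import roc_curve

__all__ = [
    "MetricsReport",
    "TestResult",
    "concordance_auc",
    "compute_metrics",
    "two_sample_ttest",
    "chi_square_contingency",
    "probability_distribution_comparison",
]


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    name: str


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    threshold: float = 0.5
    undefined: set[str] = field(default_factory=set)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("tp", "fp", "fn", "tn", "accuracy", "sensitivity",
              "specificity", "ppv", "f1", "auc", "threshold")}
        d["undefined"] = sorted(self.undefined)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def concordance_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties half).

    Computed from the rank-sum, which handles ties by average ranks; NaN if
    only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = scipy.stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Confusion counts and derived metrics at the given threshold."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if probs.shape != y.shape or probs.ndim != 1:
        raise ValueError("probabilities and labels must be aligned 1-d arrays")
    if len(y) == 0:
        raise ValueError("cannot compute metrics on empty input")
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    auc = concordance_auc(probs, y)
    roc_points: list[tuple[float, float]] = []
    if math.isnan(auc):
        undefined.add("auc")
    else:
        fpr, tpr, _ = roc_curve(y, probs)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / len(y),
        sensitivity=sens, specificity=spec, ppv=ppv, f1=f1,
        auc=auc, roc_points=roc_points, threshold=threshold,
        undefined=undefined,
    )


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-tailed t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("degenerate samples: zero combined variance")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        name="welch-t",
    )


def chi_square_contingency(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-squared on an r x c table, no continuity correction.

    All-zero columns are dropped first; at least a 2 x 2 table must remain.
    """
    tab = np.asarray(table)
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if tab.sum() == 0:
        raise ValueError("all-zero contingency table")
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 non-empty columns")
    res = scipy.stats.chi2_contingency(tab, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.dof),
        p_value=float(res.pvalue),
        name="pearson-chi2",
    )


def probability_distribution_comparison(
    correct_probabilities: Sequence[float],
    incorrect_probabilities: Sequence[float],
    n_bins: int = 10,
) -> tuple[TestResult, np.ndarray]:
    """Chi-squared comparison of predicted-probability histograms.

    Bins both groups into ``n_bins`` equal-width bins on [0, 1] (a
    probability of exactly 1 falls in the last bin), drops bins empty in
    both groups, and tests the resulting 2 x bins table.  The binned table
    is returned for inspection alongside the test result.
    """
    correct = np.asarray(correct_probabilities, dtype=float)
    incorrect = np.asarray(incorrect_probabilities, dtype=float)
    if len(correct) == 0 or len(incorrect) == 0:
        raise ValueError("both groups must be non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h_correct, _ = np.histogram(correct, bins=edges)
    h_incorrect, _ = np.histogram(incorrect, bins=edges)
    table = np.vstack([h_correct, h_incorrect])
    usable = table.sum(axis=0) > 0
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable probability bins")
    result = chi_square_contingency(table[:, usable])
    return result, table[:, usable]
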