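"""Evaluation statistics for grading performance and annotation agreement.

Covers one-vs-rest precision/recall/F1, grade confusion matrices with
accuracy, the McNemar test for paired classifier comparison, and Fleiss'
kappa for multi-rater agreement. Zero-denominator conventions are explicit:
a precision, recall or F1 whose denominator vanishes is reported as 0 and
flagged, rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

GRADE_CLASSES = ["Normal", "I", "II", "III", "IV"]

#: Discordant-pair total at or above which the continuity-corrected
#: chi-square approximation is used instead of the exact binomial test.
MCNEMAR_EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class CountTriple:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def precision_recall_f1(c: CountTriple) -> PRF:
    """One-vs-rest precision, recall and their harmonic mean.

    Any zero denominator yields 0 for the affected quantity and sets the
    ``degenerate`` flag.
    """
    degenerate = False
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, degenerate = 0.0, True
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return PRF(precision, recall, f1, degenerate)


@dataclass
class ConfusionResult:
    matrix: np.ndarray  # rows = truth, columns = prediction
    classes: list[str]
    accuracy: float
    per_class: dict[str, CountTriple]

    def macro_f1(self) -> float:
        return float(np.mean([precision_recall_f1(c).f1 for c in self.per_class.values()]))

    def micro_prf(self) -> PRF:
        tp = sum(c.tp for c in self.per_class.values())
        fp = sum(c.fp for c in self.per_class.values())
        fn = sum(c.fn for c in self.per_class.values())
        return precision_recall_f1(CountTriple(tp, fp, fn))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.classes, columns=self.classes).to_csv(path)


def confusion_and_accuracy(pred, truth, classes: list[str] | None = None) -> ConfusionResult:
    """Confusion matrix, accuracy and per-class one-vs-rest counts."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    if classes is None:
        classes = GRADE_CLASSES
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    matrix = np.zeros((k, k), dtype=int)
    for p, t in zip(pred, truth):
        matrix[index[str(t)], index[str(p)]] += 1
    total = matrix.sum()
    accuracy = float(np.trace(matrix) / total) if total else 0.0
    per_class = {}
    for c, i in index.items():
        tp = int(matrix[i, i])
        fp = int(matrix[:, i].sum() - tp)
        fn = int(matrix[i, :].sum() - tp)
        per_class[c] = CountTriple(tp, fp, fn)
    return ConfusionResult(matrix=matrix, classes=list(classes),
                           accuracy=accuracy, per_class=per_class)


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    method: str  # "exact-binomial" or "chi2-continuity"
    degenerate: bool = False


def mcnemar_test(b: int, c: int,
                 exact_threshold: int = MCNEMAR_EXACT_THRESHOLD) -> McNemarResult:
    """Paired comparison of two classifiers from their discordant counts.

    `b` and `c` are the two off-diagonal cells of the 2x2 agreement table
    (cases one classifier got right and the other wrong). For
    ``b + c >= exact_threshold`` the continuity-corrected chi-square
    statistic (|b-c|-1)^2/(b+c) with 1 df is used; below it, the exact
    two-sided binomial test with success probability 1/2.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(0.0, 1.0, "exact-binomial", degenerate=True)
    statistic = max(abs(b - c) - 1, 0) ** 2 / n
    if n >= exact_threshold:
        p = float(stats.chi2.sf(statistic, df=1))
        return McNemarResult(float(statistic), min(p, 1.0), "chi2-continuity")
    p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
    return McNemarResult(float(statistic), p, "exact-binomial")


def fleiss_kappa(rating_counts, n_raters: int) -> float:
    """Fleiss' kappa for agreement among a fixed number of raters.

    `rating_counts` is a subjects x categories table whose entry (i, j) is the
    number of raters assigning subject i to category j; each row must sum to
    `n_raters`.
    """
    table = np.asarray(rating_counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("rating_counts must be 2-D (subjects x categories)")
    if n_raters < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    if not np.all(table.sum(axis=1) == n_raters):
        raise ValueError("every row of rating_counts must sum to n_raters")
    n_subjects = table.shape[0]
    p_cat = table.sum(axis=0) / (n_subjects * n_raters)
    p_i = ((table ** 2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_e = float((p_cat ** 2).sum())
    if math.isclose(p_e, 1.0):
        return 1.0  # all ratings in one category: observed = expected = 1
    return float((p_bar - p_e) / (1.0 - p_e))


def dice_coefficient(pred_mask, true_mask, label: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) for one label; 1.0 if both absent."""
    a = np.asarray(pred_mask) == label
    b = np.asarray(true_mask) == label
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def mean_foreground_dice(pred_mask, true_mask, labels=range(1, 7)) -> float:
    return float(np.mean([dice_coefficient(pred_mask, true_mask, l) for l in labels]))
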