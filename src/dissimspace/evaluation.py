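"""Accuracy, one-vs-all AUC, and Wilcoxon signed-rank method comparison.

Accuracy is reported in percent.  Multiclass AUC follows the one-vs-all
convention: for each class, the binary AUC of that class's score column
against the indicator (truth == class), averaged over classes; tied scores
get half credit.  Paired method comparisons across datasets/folds use the
Wilcoxon signed-rank test with zero differences dropped (the Pratt variant
is available).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from dissimspace.classify import ScoreMatrix


@dataclass
class EvalReport:
    accuracy: float          # percent
    auc: float               # one-vs-all average, in [0, 1]
    per_class_auc: list[float] = field(default_factory=list)
    n: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must be a percentage")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """100 * (number correct) / n."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, nonempty")
    return 100.0 * float(np.mean(predicted == truth))


def auc_ova(scores: ScoreMatrix, truth: np.ndarray,
            class_labels: np.ndarray | None = None) -> tuple[float, list[float]]:
    """One-vs-all AUC: mean over classes of the binary AUC of the class's
    score column vs the class indicator.  Classes absent from truth are
    skipped with a warning.  Returns (mean_auc, per_class_aucs)."""
    truth = np.asarray(truth)
    if scores.c < 2:
        raise ValueError("need at least 2 classes")
    labels = (np.asarray(class_labels) if class_labels is not None
              else np.arange(scores.c))
    per_class: list[float] = []
    for j, lab in enumerate(labels):
        positives = truth == lab
        if positives.all() or not positives.any():
            warnings.warn(f"class {lab} absent from one side of truth; skipped",
                          stacklevel=2)
            per_class.append(float("nan"))
            continue
        per_class.append(float(roc_auc_score(positives, scores.scores[:, j])))
    valid = [a for a in per_class if not np.isnan(a)]
    if not valid:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(valid)), per_class


def evaluate(scores: ScoreMatrix, truth: np.ndarray,
             class_labels: np.ndarray | None = None) -> EvalReport:
    labels = (np.asarray(class_labels) if class_labels is not None
              else np.arange(scores.c))
    predicted = labels[scores.decisions()]
    mean_auc, per_class = auc_ova(scores, truth, labels)
    return EvalReport(accuracy(predicted, truth), mean_auc,
                      [float(a) for a in per_class], n=len(truth))


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    degenerate: bool = False  # all differences were zero


def wilcoxon_compare(acc_a: np.ndarray, acc_b: np.ndarray,
                     zero_method: str = "wilcox") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-fold accuracies.

    Zero differences are dropped by default (``wilcox``); pass
    ``zero_method='pratt'`` to keep them in the ranking.  Identical vectors
    give a degenerate (flagged) result rather than an error.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired vectors must be equal-length, nonempty")
    diffs = a - b
    nonzero = int(np.count_nonzero(diffs))
    if nonzero == 0:
        return WilcoxonResult(0.0, 1.0, 0, degenerate=True)
    res = stats.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), nonzero)
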