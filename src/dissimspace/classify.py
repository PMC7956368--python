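"""One-vs-all SVM on dissimilarity vectors, and classifier score fusion.

The base classifier is a linear one-vs-all SVM (C = 1 by default): one
binary margin per class, decision by highest confidence.  Ensembles fuse
member score matrices by the sum rule -- optionally after z-normalization
(mean 0, sd 1, population convention, statistics pooled over a reference
matrix, normally the training-fold scores) and with per-member weights.
A weighted sum with weights (4, 1) reproduces the published fusion of a
four-CNN ensemble with a Siamese ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


@dataclass
class ScoreMatrix:
    """Per-sample per-class confidences; the currency of fusion."""

    scores: np.ndarray  # (n, c)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be n x c")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def c(self) -> int:
        return self.scores.shape[1]

    def decisions(self) -> np.ndarray:
        return self.scores.argmax(axis=1)

    def save(self, path: str) -> None:
        df = pd.DataFrame(self.scores,
                          columns=[f"class_{j}" for j in range(self.c)])
        df.insert(0, "sample", np.arange(self.n))
        with open(path, "w") as fh:
            fh.write(f"# source_id: {self.source_id}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def load(cls, path: str) -> "ScoreMatrix":
        source_id = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# source_id:"):
                source_id = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        cols = [c for c in df.columns if c.startswith("class_")]
        return cls(df[cols].to_numpy(), source_id=source_id)


@dataclass
class EnsembleSpec:
    """Which topologies, prototype counts, and representations are fused."""

    topologies: tuple[int, ...]
    kc_grid: tuple[int, ...]
    representations: tuple[str, ...] = ("original",)


@dataclass
class OvaSvm:
    """One-vs-all linear SVM wrapper with signed-margin confidences."""

    model: Pipeline
    classes: np.ndarray

    def score_matrix(self, design: np.ndarray, source_id: str = "") -> ScoreMatrix:
        margins = self.model.decision_function(design)
        if margins.ndim == 1:  # binary case: expand to two columns
            margins = np.column_stack([-margins, margins])
        return ScoreMatrix(margins, source_id=source_id)

    def predict(self, design: np.ndarray) -> np.ndarray:
        return self.classes[self.score_matrix(design).decisions()]


def train_ova_svm(design: np.ndarray, labels: np.ndarray,
                  C: float = 1.0) -> OvaSvm:
    """Fit c binary linear SVMs (one against all); decision = argmax margin.

    Columns are standardized on the training design matrix first: the
    dissimilarity scores of saturated pair scorers can live on very small
    scales, and an unscaled margin fit is then poorly calibrated across
    the one-vs-all machines.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    svm = make_pipeline(StandardScaler(), LinearSVC(C=C))  # one-vs-rest
    svm.fit(design, labels)
    return OvaSvm(svm, classes)


def znorm(scores: ScoreMatrix, reference: ScoreMatrix | None = None) -> ScoreMatrix:
    """Normalize to mean 0, sd 1 (population sd), statistics pooled over
    every entry of the reference matrix (self by default)."""
    ref = reference if reference is not None else scores
    if ref.n == 0:
        raise ValueError("empty reference")
    mu = float(ref.scores.mean())
    sd = float(ref.scores.std())  # population convention (ddof=0)
    if sd == 0.0:
        warnings.warn("zero standard deviation in z-normalization reference; "
                      "scores replaced by zeros", stacklevel=2)
        return ScoreMatrix(np.zeros_like(scores.scores), scores.source_id)
    return ScoreMatrix((scores.scores - mu) / sd, scores.source_id)


def sum_rule(members: list[ScoreMatrix]) -> ScoreMatrix:
    """Elementwise sum of aligned member score matrices."""
    if not members:
        raise ValueError("no members to fuse")
    shape = members[0].scores.shape
    for m in members[1:]:
        if m.scores.shape != shape:
            raise ValueError("member score matrices must share shape")
    total = np.sum([m.scores for m in members], axis=0)
    return ScoreMatrix(total, source_id="+".join(m.source_id for m in members))


def weighted_sum(member_sets: list[tuple[ScoreMatrix, float]],
                 references: list[ScoreMatrix] | None = None) -> ScoreMatrix:
    """Sum of w_i * znorm(member_i); references default to each member itself."""
    if not member_sets:
        raise ValueError("no members to fuse")
    if any(w <= 0 for _, w in member_sets):
        raise ValueError("weights must be positive")
    refs = references or [None] * len(member_sets)
    normed = [znorm(m, r) for (m, _), r in zip(member_sets, refs)]
    shape = normed[0].scores.shape
    for m in normed[1:]:
        if m.scores.shape != shape:
            raise ValueError("member score matrices must share shape")
    total = np.sum([w * m.scores for m, (_, w) in zip(normed, member_sets)], axis=0)
    return ScoreMatrix(total, source_id="+".join(m.source_id for m, _ in member_sets))


def ensemble_size(spec: EnsembleSpec) -> int:
    """Number of fused classifiers per representation: |topologies| * |kc_grid|."""
    if not spec.topologies or not spec.kc_grid:
        raise ValueError("topologies and kc_grid must be nonempty")
    return len(spec.topologies) * len(spec.kc_grid)
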