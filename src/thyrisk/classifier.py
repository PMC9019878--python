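"""Classifier interpretation layer: additive genomic score and call thresholds.

Two classifiers operate on an indeterminate nodule:

* an **RNA expression classifier** producing a percentage score; a score
  strictly above 10% is called positive (high cancer probability);
* a **genomic classifier (GC)** that assigns each detected DNA/RNA alteration
  a percentage weight and combines them into a single score, positive
  strictly above 70% ("≤ threshold accepted" is negative in both cases).

The combination rule is additive with saturation by default
(``min(100, Σ wᵢ)`` — the sum of the individual values, capped so the score
remains a percentage); a ``noisy_or`` alternative
(``100·(1 − Π(1 − wᵢ/100))``) is offered because an unbounded sum cannot
itself be a percentage.  Both rules agree on singletons and are
permutation-invariant and monotone under appending evidence.

The estimators follow the scikit-learn protocol (``fit`` validates and
freezes parameters into trailing-underscore attributes; ``decision_function``
returns the percentage score; ``predict`` the 0/1 call) and compose with
sklearn model selection.  The module-level functions are the primitive
operations the estimators wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .alterations import Alteration, DEFAULT_WEIGHT_TABLE, WeightTable, parse_alteration_list
from .errors import DomainError

__all__ = [
    "RNA_THRESHOLD",
    "GC_THRESHOLD",
    "Thresholds",
    "ClassifierResult",
    "score_alterations",
    "combine_scores",
    "gc_score",
    "classify",
    "evaluate_nodule",
    "GenomicClassifier",
    "ExpressionScoreClassifier",
]

RNA_THRESHOLD = 10.0  # percent; expression call positive strictly above
GC_THRESHOLD = 70.0  # percent; genomic-classifier call positive strictly above


@dataclass(frozen=True)
class Thresholds:
    rna_threshold: float = RNA_THRESHOLD
    gc_threshold: float = GC_THRESHOLD

    def __post_init__(self):
        for t in (self.rna_threshold, self.gc_threshold):
            if not (0.0 <= t <= 100.0):
                raise DomainError(f"threshold must be in [0, 100], got {t}")


@dataclass(frozen=True)
class ClassifierResult:
    """Scores, calls and the per-alteration contributions behind the GC score."""

    rna_score: float | None
    rna_call: str | None
    gc_score: float
    gc_call: str
    contributing_values: tuple[tuple[Alteration, float], ...]


def score_alterations(
    alterations: Sequence[Alteration], weights: WeightTable = DEFAULT_WEIGHT_TABLE
) -> list[tuple[Alteration, float]]:
    """One (alteration, percentage weight) pair per alteration, order preserved."""
    return [(a, weights.lookup(a)) for a in alterations]


def combine_scores(values: Iterable[float], rule: str = "saturating_sum") -> float:
    """Combine per-alteration percentages into one GC score in [0, 100].

    Empty input scores 0 (no evidence of malignancy).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size and (vals.min() < 0.0 or vals.max() > 100.0):
        raise DomainError(f"per-alteration values must be in [0, 100], got {vals}")
    if vals.size == 0:
        return 0.0
    if rule == "saturating_sum":
        return float(min(100.0, vals.sum()))
    if rule == "noisy_or":
        return float(100.0 * (1.0 - np.prod(1.0 - vals / 100.0)))
    raise DomainError(f"unknown combination rule {rule!r}")


gc_score = combine_scores  # domain-named alias


def classify(score: float, threshold: float) -> str:
    """Binary call: ``positive`` iff score strictly exceeds the threshold.

    The threshold itself is accepted as negative (``classify(70, 70) ==
    "negative"``), matching the "≤ threshold accepted was negative" rule.
    """
    for v in (score, threshold):
        if not (0.0 <= v <= 100.0):
            raise DomainError(f"score and threshold must be in [0, 100], got {v}")
    return "positive" if score > threshold else "negative"


def evaluate_nodule(
    alterations: Sequence[Alteration],
    weights: WeightTable = DEFAULT_WEIGHT_TABLE,
    rna_score: float | None = None,
    thresholds: Thresholds = Thresholds(),
    rule: str | None = None,
) -> ClassifierResult:
    """Full interpretation of one nodule: GC score/call plus RNA call if scored."""
    contrib = score_alterations(alterations, weights)
    score = combine_scores((v for _, v in contrib), rule or weights.combination_rule)
    return ClassifierResult(
        rna_score=rna_score,
        rna_call=None if rna_score is None else classify(rna_score, thresholds.rna_threshold),
        gc_score=score,
        gc_call=classify(score, thresholds.gc_threshold),
        contributing_values=tuple(contrib),
    )


def _as_alteration_lists(X) -> list[list[Alteration]]:
    """Accept a DataFrame with an ``alterations`` column, a Series, or a
    sequence whose items are alteration lists or semicolon-joined strings."""
    if isinstance(X, pd.DataFrame):
        if "alterations" not in X.columns:
            raise DomainError("DataFrame input requires an 'alterations' column")
        X = X["alterations"]
    if isinstance(X, pd.Series):
        X = X.tolist()
    out: list[list[Alteration]] = []
    for item in X:
        if isinstance(item, str) or item is None or (isinstance(item, float) and np.isnan(item)):
            out.append(parse_alteration_list(item if isinstance(item, str) else ""))
        else:
            out.append(list(item))
    return out


class GenomicClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based additive genomic classifier as a scikit-learn estimator.

    Parameters
    ----------
    weight_table
        Per-alteration percentage weights; ``None`` uses the package default.
    threshold
        Positivity threshold in percent (strictly-greater rule).
    rule
        ``"saturating_sum"`` (default) or ``"noisy_or"``.

    The classifier is fully specified by its parameters — ``fit`` validates
    them and records ``classes_`` but estimates nothing from data, like
    sklearn's ``DummyClassifier``; it exists so the object composes with
    pipelines and ``cross_val_score``.
    """

    def __init__(
        self,
        weight_table: WeightTable | None = None,
        threshold: float = GC_THRESHOLD,
        rule: str = "saturating_sum",
    ):
        self.weight_table = weight_table
        self.threshold = threshold
        self.rule = rule

    def fit(self, X, y=None):
        if not (0.0 <= self.threshold <= 100.0):
            raise DomainError(f"threshold must be in [0, 100], got {self.threshold}")
        combine_scores([], self.rule)  # validates the rule name
        self.weight_table_ = self.weight_table or DEFAULT_WEIGHT_TABLE
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        """GC score in percent for each nodule."""
        if not hasattr(self, "weight_table_"):
            self.fit(X)
        return np.array(
            [
                combine_scores(
                    (v for _, v in score_alterations(alts, self.weight_table_)), self.rule
                )
                for alts in _as_alteration_lists(X)
            ]
        )

    def predict(self, X) -> np.ndarray:
        """0/1 call per nodule (1 = positive, score strictly above threshold)."""
        return (self.decision_function(X) > self.threshold).astype(int)

    def predict_calls(self, X) -> np.ndarray:
        return np.where(self.predict(X) == 1, "positive", "negative")


class ExpressionScoreClassifier(ClassifierMixin, BaseEstimator):
    """Threshold rule on a continuous expression-classifier score.

    The upstream model producing the score (an SVM over expression profiles)
    is out of scope; its score arrives as data, here or from the cohort
    simulator, and this estimator applies the strictly-greater percentage
    threshold (default 10%).
    """

    def __init__(self, threshold: float = RNA_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not (0.0 <= self.threshold <= 100.0):
            raise DomainError(f"threshold must be in [0, 100], got {self.threshold}")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _scores(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            col = "rna_score" if "rna_score" in X.columns else X.columns[0]
            X = X[col]
        arr = np.asarray(X, dtype=float).reshape(-1)
        if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 100.0):
            raise DomainError("scores must be percentages in [0, 100]")
        return arr

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit(X)
        return (self._scores(X) > self.threshold).astype(int)

    def predict_calls(self, X) -> np.ndarray:
        return np.where(self.predict(X) == 1, "positive", "negative")
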