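"""Diagnostic accuracy against histopathology.

Confusion tables under an explicit borderline policy, proportion metrics
with confidence intervals (Wilson score by default, Wald with continuity
correction as the alternative dialect), risk of malignancy, resection-rate
comparison, Pearson chi-squared 2×2 comparisons, the Mann–Whitney AUC and
the alteration risk-tier summaries.

Histopathology of the resected nodule is the gold standard throughout; the
borderline policy (whether NIFTP / WT-UMP count as disease) is a parameter
of every truth-dependent operation, defaulting to ``as_malignant`` because
those lesions are managed surgically.  Undefined metrics raise
:class:`~thyrisk.errors.UndefinedMetricError`; nothing returns silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .alterations import (
    DEFAULT_TIER_MAP,
    RAS_FAMILY,
    RiskTier,
    TierMap,
    assign_tier,
    parse_alteration_list,
)
from .errors import ContractError, DomainError, UndefinedMetricError
from .nodules import UNRESECTED, histology_class, truth_labels

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "ComparisonResult",
    "confusion_table",
    "binary_metrics",
    "wilson_ci",
    "wald_cc_ci",
    "proportion_estimate",
    "rom",
    "resection_rates",
    "chi2_2x2",
    "compare_proportions",
    "auc_mann_whitney",
    "alteration_summaries",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts of classifier call against histologic truth."""

    tp: int
    fp: int
    tn: int
    fn: int
    borderline_policy: str = "as_malignant"

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise DomainError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        if self.total == 0:
            raise UndefinedMetricError("prevalence", "empty table")
        return (self.tp + self.fn) / self.total


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion metric with its confidence interval and CI dialect."""

    metric: str
    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    ci_method: str
    level: float = 0.95

    def __str__(self):
        pct = 100 * self.point
        if self.ci_method == "none":
            return f"{self.metric} = {pct:.1f}% ({self.numerator}/{self.denominator})"
        return (
            f"{self.metric} = {pct:.1f}% ({self.numerator}/{self.denominator}; "
            f"{100 * self.level:.0f}% {self.ci_method} CI "
            f"{100 * self.ci_low:.1f}–{100 * self.ci_high:.1f}%)"
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson chi-squared comparison of a 2×2 count table (df = 1)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi2_stat: float
    df: int
    p_value: float
    correction: str = "none"


def confusion_table(
    records: pd.DataFrame,
    call_field: str = "gc_call",
    borderline_policy: str = "as_malignant",
) -> ConfusionTable:
    """Cross-tabulate a call column against histologic truth.

    Every record must be resected with known histology and a non-missing
    call; unresected rows are a contract violation, not silently dropped —
    restricting to the resected subset is the caller's explicit, visible
    step because it is exactly where verification bias enters.
    """
    if len(records) == 0:
        return ConfusionTable(0, 0, 0, 0, borderline_policy)
    if not records["resected"].all() or (records["histology"] == UNRESECTED).any():
        raise ContractError("confusion_table requires resected records with known histology")
    calls = records[call_field]
    if calls.isna().any():
        raise ContractError(f"missing {call_field!r} values")
    pos_call = calls.eq("positive")
    if not (pos_call | calls.eq("negative")).all():
        bad = calls[~(pos_call | calls.eq("negative"))].iloc[0]
        raise ContractError(f"calls must be positive/negative, got {bad!r}")
    truth = truth_labels(records["histology"], borderline_policy)
    return ConfusionTable(
        tp=int((pos_call & truth).sum()),
        fp=int((pos_call & ~truth).sum()),
        tn=int((~pos_call & ~truth).sum()),
        fn=int((~pos_call & truth).sum()),
        borderline_policy=borderline_policy,
    )


def _z(level: float) -> float:
    if not (0.0 < level < 1.0):
        raise DomainError(f"confidence level must be in (0, 1), got {level}")
    return float(stats.norm.ppf((1.0 + level) / 2.0))


def wilson_ci(k, n, level: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion (vectorises over k, n)."""
    k_arr, n_arr = np.asarray(k), np.asarray(n)
    if np.any(n_arr <= 0):
        raise UndefinedMetricError("proportion", "n must be positive")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise DomainError("need 0 <= k <= n")
    low, high = proportion_confint(k_arr, n_arr, alpha=1.0 - level, method="wilson")
    if np.ndim(k) == 0 and np.ndim(n) == 0:
        return float(low), float(high)
    return np.asarray(low, float), np.asarray(high, float)


def wald_cc_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald interval with continuity correction, clipped to [0, 1].

    ``p̂ ± (z·√(p̂(1−p̂)/n) + 1/(2n))`` — the dialect that reproduces some
    published interval bounds that the Wilson score interval does not.
    """
    if n <= 0:
        raise UndefinedMetricError("proportion", "n must be positive")
    if not (0 <= k <= n):
        raise DomainError("need 0 <= k <= n")
    p = k / n
    half = _z(level) * np.sqrt(p * (1.0 - p) / n) + 1.0 / (2.0 * n)
    return float(max(0.0, p - half)), float(min(1.0, p + half))


def proportion_estimate(
    metric: str, k: int, n: int, ci_method: str = "wilson", level: float = 0.95
) -> MetricEstimate:
    """Package k/n with the requested interval dialect into a MetricEstimate."""
    if n <= 0:
        raise UndefinedMetricError(metric, f"denominator is {n}")
    if ci_method == "wilson":
        lo, hi = wilson_ci(k, n, level)
    elif ci_method == "wald_cc":
        lo, hi = wald_cc_ci(k, n, level)
    elif ci_method == "none":
        lo = hi = k / n
    else:
        raise DomainError(f"unknown CI method {ci_method!r}")
    return MetricEstimate(metric, int(k), int(n), k / n, lo, hi, ci_method, level)


def binary_metrics(
    ct: ConfusionTable, ci_method: str = "wilson", level: float = 0.95
) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV, NPV and accuracy from one 2×2 table."""
    pairs = {
        "sensitivity": (ct.tp, ct.tp + ct.fn),
        "specificity": (ct.tn, ct.tn + ct.fp),
        "ppv": (ct.tp, ct.tp + ct.fp),
        "npv": (ct.tn, ct.tn + ct.fn),
        "accuracy": (ct.tp + ct.tn, ct.total),
    }
    return {m: proportion_estimate(m, k, n, ci_method, level) for m, (k, n) in pairs.items()}


def rom(
    records: pd.DataFrame,
    borderline_policy: str = "as_malignant",
    ci_method: str = "wilson",
    level: float = 0.95,
) -> MetricEstimate:
    """Risk of malignancy: diseased fraction of the resected nodules."""
    if len(records) == 0:
        raise UndefinedMetricError("rom", "no resected records")
    if not records["resected"].all() or (records["histology"] == UNRESECTED).any():
        raise ContractError("rom requires resected records with known histology")
    truth = truth_labels(records["histology"], borderline_policy)
    return proportion_estimate("rom", int(truth.sum()), len(records), ci_method, level)


def resection_rates(
    records: pd.DataFrame,
    call_field: str = "gc_call",
    correction: str = "none",
    ci_method: str = "wilson",
    level: float = 0.95,
) -> tuple[MetricEstimate, MetricEstimate, ComparisonResult]:
    """Resection rate in call-positive vs call-negative nodules, compared.

    Returns (positive-stratum rate, negative-stratum rate, chi-squared
    comparison of resected×call).  Whether molecular results drive surgery
    is the question this answers: under management blind to the test, the
    two rates should not differ beyond chance.
    """
    calls = records[call_field]
    if calls.isna().any():
        raise ContractError(f"every record needs a {call_field!r} value")
    pos = records[calls.eq("positive")]
    neg = records[calls.eq("negative")]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("resection_rate", "a call stratum is empty")
    rp, rn = int(pos["resected"].sum()), int(neg["resected"].sum())
    cmp = chi2_2x2(rp, len(pos) - rp, rn, len(neg) - rn, correction=correction)
    return (
        proportion_estimate("resection_rate", rp, len(pos), ci_method, level),
        proportion_estimate("resection_rate", rn, len(neg), ci_method, level),
        cmp,
    )


def chi2_2x2(a: int, b: int, c: int, d: int, correction: str = "none") -> ComparisonResult:
    """Pearson chi-squared test on the 2×2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default; ``correction="yates"`` applies it.
    A zero expected cell makes the statistic undefined and raises.
    """
    if correction not in ("none", "yates"):
        raise DomainError(f"unknown correction {correction!r}")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise DomainError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DomainError("zero expected cell: a margin of the table is empty")
    chi2_stat, p, dof, _ = stats.chi2_contingency(table, correction=(correction == "yates"))
    return ComparisonResult(
        table=((int(a), int(b)), (int(c), int(d))),
        chi2_stat=float(chi2_stat),
        df=int(dof),
        p_value=float(p),
        correction=correction,
    )


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: str = "none"
) -> ComparisonResult:
    """Chi-squared comparison of two proportions k1/n1 vs k2/n2.

    This is how a cohort's metric is set against a published comparator's
    printed numerator/denominator pair.
    """
    return chi2_2x2(k1, n1 - k1, k2, n2 - k2, correction=correction)


def auc_mann_whitney(scores, labels) -> float:
    """Empirical ROC area via the Mann–Whitney statistic.

    AUC = (wins + 0.5·ties) / (n_pos · n_neg) over all positive–negative
    score pairs, computed through midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError("scores and labels must be aligned 1-d sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("AUC requires at least one positive and one negative label")
    ranks = stats.rankdata(s)  # midranks handle ties as half-wins
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def alteration_summaries(
    records: pd.DataFrame,
    tier_map: TierMap = DEFAULT_TIER_MAP,
    ras_genes_only: bool = True,
) -> dict[str, MetricEstimate]:
    """Risk-tier summaries over a resected cohort.

    ``high_risk_malignant_fraction``
        Fraction of malignant nodules carrying at least one high-risk
        alteration (BRAF V600E, TERT, fusion), each nodule counted once.
    ``ras_alone_neoplasia_fraction``
        Among nodules whose only alterations are RAS-family mutations
        (NRAS/HRAS/KRAS), the fraction with malignant or borderline
        (NIFTP / WT-UMP) histology.  ``ras_genes_only=False`` widens the
        stratum to all RAS-like-only nodules, which adds BRAF K601E
        carriers.
    """
    if (records["histology"] == UNRESECTED).any():
        raise ContractError("alteration summaries require resected records")
    alt_lists = records["alterations"].map(lambda c: parse_alteration_list(c or ""))
    tiers = alt_lists.map(lambda alts: [assign_tier(a, tier_map) for a in alts])
    classes = records["histology"].map(histology_class)

    malignant = classes.eq("malignant")
    has_high_risk = tiers.map(lambda ts: any(t is RiskTier.HIGH_RISK for t in ts))
    n_mal = int(malignant.sum())
    if n_mal == 0:
        raise UndefinedMetricError("high_risk_malignant_fraction", "no malignant nodules")
    high_risk = proportion_estimate(
        "high_risk_malignant_fraction", int((malignant & has_high_risk).sum()), n_mal
    )

    if ras_genes_only:
        in_stratum = alt_lists.map(
            lambda alts: len(alts) > 0 and all(a.gene in RAS_FAMILY for a in alts)
        )
    else:
        in_stratum = [
            len(ts) > 0 and all(t is RiskTier.RAS_LIKE for t in ts) for ts in tiers
        ]
        in_stratum = pd.Series(in_stratum, index=records.index)
    n_ras = int(in_stratum.sum())
    if n_ras == 0:
        raise UndefinedMetricError("ras_alone_neoplasia_fraction", "no RAS-only nodules")
    neoplastic = classes.isin(["malignant", "borderline"])
    ras_alone = proportion_estimate(
        "ras_alone_neoplasia_fraction", int((in_stratum & neoplastic).sum()), n_ras
    )
    return {
        "high_risk_malignant_fraction": high_risk,
        "ras_alone_neoplasia_fraction": ras_alone,
    }
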