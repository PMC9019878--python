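"""Synthetic indeterminate-nodule cohorts with controllable operating points.

No individual-level data accompany the published analysis, so every
downstream stage is exercised on simulated cohorts that reproduce the
*statistical structure* the analysis assumes:

* a three-class outcome mixture (benign / borderline / malignant) with the
  resected-cohort composition 15:10:33 by default;
* class-conditional alteration frequencies read off the published
  histology×alteration listing (per-alteration independent Bernoulli draws);
* class-conditional classifier scores drawn from Beta distributions
  *calibrated* so that the probability mass above the positivity threshold
  equals a requested sensitivity (diseased side) and the mass at or below it
  equals a requested specificity (benign side);
* resection decided by a per-call Bernoulli (defaults 0.43 positive / 0.35
  negative — the "management blind to the test" regime where the rates do
  not differ significantly);
* histology masked to ``unresected`` for unresected nodules by default,
  reproducing the verification bias of the real design; an explicit flag
  reveals it for simulation studies that need the latent truth.

One seeded NumPy generator drives everything: identical config and seed give
a bit-for-bit identical cohort.

Note the simulated genomic-classifier score is drawn from its calibrated
Beta rather than recomputed from the simulated alterations — the simulator's
contract is the operating point, not the weight arithmetic, which has its
own module and tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .classifier import GC_THRESHOLD, RNA_THRESHOLD
from .errors import CalibrationError, ConfigError
from .nodules import (
    BENIGN_HISTOLOGIES,
    BORDERLINE_HISTOLOGIES,
    MALIGNANT_HISTOLOGIES,
    NODULE_COLUMNS,
    UNRESECTED,
)
from .performance import wilson_ci

__all__ = [
    "BetaParams",
    "calibrate_score_distributions",
    "CohortConfig",
    "generate_cohort",
    "parameter_recovery_study",
]


class BetaParams(NamedTuple):
    a: float
    b: float


_CAL_TOL = 1e-10  # root-finding tolerance; well inside the 1e-6 contract


def _solve_beta_tail(threshold01: float, tail_mass: float, fixed_a: float) -> BetaParams:
    """Beta(a=fixed, b) with P(X > threshold01) = tail_mass."""
    def f(log_b):
        return stats.beta.sf(threshold01, fixed_a, np.exp(log_b)) - tail_mass

    # sf is decreasing in b: bracket a sign change on the log scale
    lo, hi = -20.0, 20.0
    log_b = optimize.brentq(f, lo, hi, xtol=_CAL_TOL)
    return BetaParams(fixed_a, float(np.exp(log_b)))


def _solve_beta_head(threshold01: float, head_mass: float, fixed_b: float) -> BetaParams:
    """Beta(a, b=fixed) with P(X <= threshold01) = head_mass."""
    def f(log_a):
        return stats.beta.cdf(threshold01, np.exp(log_a), fixed_b) - head_mass

    log_a = optimize.brentq(f, -20.0, 20.0, xtol=_CAL_TOL)
    return BetaParams(float(np.exp(log_a)), fixed_b)


def calibrate_score_distributions(
    target_sens: float,
    target_spec: float,
    threshold: float = GC_THRESHOLD,
    fixed_shape: float = 4.0,
) -> tuple[BetaParams, BetaParams]:
    """Class-conditional Beta parameters hitting a requested operating point.

    Returns ``(diseased, benign)`` shape pairs on the [0, 1] scale (scores
    are percentages, i.e. 100·X) such that

    * P(100·X > threshold | diseased) = ``target_sens``
    * P(100·X ≤ threshold | benign) = ``target_spec``

    each to well within 1e-6, solved numerically with one shape fixed at
    ``fixed_shape`` (the remaining shape is the single degree of freedom; a
    Beta cannot place probability exactly 0 or 1 strictly beyond an interior
    threshold, so boundary targets raise :class:`CalibrationError`).
    """
    for name, t in (("target_sens", target_sens), ("target_spec", target_spec)):
        if not (0.0 < t < 1.0):
            raise CalibrationError(
                f"{name} must be strictly inside (0, 1), got {t}: a Beta score "
                "family cannot realise a degenerate operating point"
            )
    if not (0.0 < threshold < 100.0):
        raise CalibrationError(f"threshold must be in (0, 100), got {threshold}")
    if fixed_shape <= 0.0:
        raise CalibrationError(f"fixed_shape must be positive, got {fixed_shape}")
    t01 = threshold / 100.0
    diseased = _solve_beta_tail(t01, target_sens, fixed_shape)
    benign = _solve_beta_head(t01, target_spec, fixed_shape)
    return diseased, benign


def _default_subtype_probs() -> dict[str, dict[str, float]]:
    # resected-cohort subtype composition: 12/2/1 benign, 3/7 borderline,
    # 9/3/15/1/1/1/2/1 malignant
    counts = {
        "benign": dict(zip(BENIGN_HISTOLOGIES, (12, 2, 1))),
        "borderline": dict(zip(BORDERLINE_HISTOLOGIES, (3, 7))),
        "malignant": dict(zip(MALIGNANT_HISTOLOGIES, (9, 3, 15, 1, 1, 1, 2, 1))),
    }
    return {
        cls: {h: c / sum(sub.values()) for h, c in sub.items()}
        for cls, sub in counts.items()
    }


def _default_alteration_freqs() -> dict[str, dict[str, float]]:
    # per-class per-alteration carrier frequencies from the histology listing
    return {
        "benign": {"NRAS": 1 / 15, "HRAS": 1 / 15},
        "borderline": {"BRAF:K601E": 2 / 10, "NRAS": 3 / 10},
        "malignant": {
            "BRAF:V600E": 5 / 33,
            "NRAS": 3 / 33,
            "KRAS": 2 / 33,
            "TERT": 2 / 33,
            "ETV6-NTRK3:fusion": 4 / 33,
            "CCDC6-RET:fusion": 1 / 33,
            "NCOA4-RET:fusion": 1 / 33,
            "STRN-ALK:fusion": 1 / 33,
        },
    }


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic cohort.

    Probability vectors must sum to 1 within 1e-9.  ``borderline_scores``
    selects which side's calibrated Beta scores borderline nodules: the
    diseased side by default (borderline lesions mostly test positive), or
    explicit Beta parameters per classifier.
    """

    n_nodules: int = 140
    seed: int = 0
    bethesda_probs: dict[str, float] = field(
        default_factory=lambda: {"III": 87 / 140, "IV": 53 / 140}
    )
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"benign": 15 / 58, "borderline": 10 / 58, "malignant": 33 / 58}
    )
    subtype_probs: dict[str, dict[str, float]] = field(default_factory=_default_subtype_probs)
    alteration_freqs: dict[str, dict[str, float]] = field(
        default_factory=_default_alteration_freqs
    )
    rna_target: tuple[float, float] = (0.93, 0.40)  # (sensitivity, specificity)
    gc_target: tuple[float, float] = (0.884, 0.533)
    rna_threshold: float = RNA_THRESHOLD
    gc_threshold: float = GC_THRESHOLD
    resection_probs: dict[str, float] = field(
        default_factory=lambda: {"positive": 0.43, "negative": 0.35}
    )
    borderline_scores: str = "diseased"  # or "own" with explicit params below
    borderline_beta: dict[str, BetaParams] | None = None
    observe_unresected_histology: bool = False
    size_lognorm_mu: float = 0.0  # log median 1.0 cm
    size_lognorm_sigma: float = 0.6  # matches the 0.7–1.5 cm IQR

    def __post_init__(self):
        if self.n_nodules < 0:
            raise ConfigError(f"n_nodules must be non-negative, got {self.n_nodules}")
        for name, probs in (
            ("bethesda_probs", self.bethesda_probs),
            ("class_probs", self.class_probs),
            *((f"subtype_probs[{c}]", p) for c, p in self.subtype_probs.items()),
        ):
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        for cls, freqs in self.alteration_freqs.items():
            for alt, f_ in freqs.items():
                if not (0.0 <= f_ <= 1.0):
                    raise ConfigError(f"alteration frequency {cls}/{alt} = {f_} not in [0, 1]")
        for call, p in self.resection_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"resection probability for {call} not in [0, 1]")
        if self.borderline_scores not in ("diseased", "own"):
            raise ConfigError(f"unknown borderline_scores mode {self.borderline_scores!r}")
        if self.borderline_scores == "own" and not self.borderline_beta:
            raise ConfigError("borderline_scores='own' requires borderline_beta parameters")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.borderline_beta is not None:
            d["borderline_beta"] = {k: list(v) for k, v in self.borderline_beta.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if d.get("borderline_beta"):
            d["borderline_beta"] = {
                k: BetaParams(*v) for k, v in d["borderline_beta"].items()
            }
        for key in ("rna_target", "gc_target"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw_scores(
    rng: np.random.Generator,
    classes: np.ndarray,
    target: tuple[float, float],
    threshold: float,
    borderline_mode: str,
    borderline_beta: BetaParams | None,
) -> np.ndarray:
    diseased, benign = calibrate_score_distributions(target[0], target[1], threshold)
    scores = np.empty(len(classes))
    is_benign = classes == "benign"
    is_borderline = classes == "borderline"
    is_diseased = ~is_benign if borderline_mode == "diseased" else classes == "malignant"
    scores[is_benign] = 100.0 * rng.beta(benign.a, benign.b, is_benign.sum())
    scores[is_diseased] = 100.0 * rng.beta(diseased.a, diseased.b, is_diseased.sum())
    if borderline_mode == "own":
        assert borderline_beta is not None
        scores[is_borderline] = 100.0 * rng.beta(
            borderline_beta.a, borderline_beta.b, is_borderline.sum()
        )
    return scores


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one synthetic cohort as a nodule-table DataFrame.

    The same config (including seed) always yields the identical frame.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodules
    if n == 0:
        return pd.DataFrame(columns=NODULE_COLUMNS)

    class_names = list(config.class_probs)
    classes = rng.choice(class_names, size=n, p=list(config.class_probs.values()))

    histology = np.empty(n, dtype=object)
    for cls in class_names:
        mask = classes == cls
        subs = config.subtype_probs[cls]
        histology[mask] = rng.choice(list(subs), size=mask.sum(), p=list(subs.values()))

    alt_cells = np.full(n, "", dtype=object)
    for cls, freqs in config.alteration_freqs.items():
        mask = classes == cls
        if not mask.sum() or not freqs:
            continue
        carriers = {
            alt: rng.random(mask.sum()) < f_ for alt, f_ in freqs.items()
        }
        cells = [
            ";".join(alt for alt in freqs if carriers[alt][i])
            for i in range(mask.sum())
        ]
        alt_cells[mask] = cells

    rna_score = _draw_scores(
        rng, classes, config.rna_target, config.rna_threshold,
        config.borderline_scores,
        (config.borderline_beta or {}).get("rna"),
    )
    gc_score = _draw_scores(
        rng, classes, config.gc_target, config.gc_threshold,
        config.borderline_scores,
        (config.borderline_beta or {}).get("gc"),
    )
    rna_call = np.where(rna_score > config.rna_threshold, "positive", "negative")
    gc_call = np.where(gc_score > config.gc_threshold, "positive", "negative")

    p_resect = np.where(
        gc_call == "positive",
        config.resection_probs["positive"],
        config.resection_probs["negative"],
    )
    resected = rng.random(n) < p_resect

    observed = histology.copy()
    if not config.observe_unresected_histology:
        observed[~resected] = UNRESECTED

    bethesda = rng.choice(
        list(config.bethesda_probs), size=n, p=list(config.bethesda_probs.values())
    )
    size_cm = np.round(
        np.exp(rng.normal(config.size_lognorm_mu, config.size_lognorm_sigma, n)), 2
    )
    size_cm = np.maximum(size_cm, 0.1)

    frame = pd.DataFrame(
        {
            "nodule_id": [f"S{i + 1:05d}" for i in range(n)],
            "patient_id": [f"SP{i + 1:05d}" for i in range(n)],
            "bethesda": bethesda,
            "size_cm": size_cm,
            "histology": observed,
            "resected": resected,
            "alterations": alt_cells,
            "rna_score": np.round(rna_score, 4),
            "gc_score": np.round(gc_score, 4),
            "rna_call": rna_call,
            "gc_call": gc_call,
        }
    )
    return frame[NODULE_COLUMNS]


def parameter_recovery_study(
    n_replicates: int = 500,
    n: int = 5000,
    target_sens: float = 0.93,
    target_spec: float = 0.40,
    threshold: float = GC_THRESHOLD,
    prevalence: float = 43 / 58,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, float]:
    """Coverage check: do Wilson CIs from simulated cohorts recover the truth?

    For each replicate a resected cohort of ``n`` nodules is drawn with
    diseased prevalence ``prevalence`` and scores from the Beta pair
    calibrated to (``target_sens``, ``target_spec``); the replicate's
    estimated sensitivity and specificity each get a Wilson interval, and
    the study reports the fraction of replicates whose interval covers the
    calibrated true value, per metric.
    """
    rng = np.random.default_rng(seed)
    diseased, benign = calibrate_score_distributions(target_sens, target_spec, threshold)
    t01 = threshold / 100.0

    n_dis = rng.binomial(n, prevalence, size=n_replicates)
    n_ben = n - n_dis
    # tail/head events of the calibrated Betas, drawn per nodule
    tp = np.array(
        [int((rng.beta(diseased.a, diseased.b, nd) > t01).sum()) for nd in n_dis]
    )
    tn = np.array(
        [int((rng.beta(benign.a, benign.b, nb) <= t01).sum()) for nb in n_ben]
    )
    sens_lo, sens_hi = wilson_ci(tp, n_dis, level)
    spec_lo, spec_hi = wilson_ci(tn, n_ben, level)
    cover_sens = float(((sens_lo <= target_sens) & (target_sens <= sens_hi)).mean())
    cover_spec = float(((spec_lo <= target_spec) & (target_spec <= spec_hi)).mean())
    return {
        "n_replicates": n_replicates,
        "n": n,
        "sensitivity_coverage": cover_sens,
        "specificity_coverage": cover_spec,
        "mean_sensitivity": float((tp / n_dis).mean()),
        "mean_specificity": float((tn / n_ben).mean()),
    }
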