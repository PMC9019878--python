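"""Predictive values as functions of disease prevalence; rule-in/rule-out.

Sensitivity and specificity are properties of a test; PPV and NPV are not —
they depend on the prevalence of disease in the tested population through
Bayes' theorem:

    PPV(p) = sens·p / (sens·p + (1 − spec)(1 − p))
    NPV(p) = spec(1 − p) / (spec(1 − p) + (1 − sens)·p)

A classifier validated in a high-prevalence setting (risk of malignancy
~74% among resected indeterminate nodules) can carry a high PPV yet a
mediocre NPV, and vice versa at North-American prevalences of 10–40%.  The
*crossover prevalence* — where NPV (or PPV) crosses a clinically chosen
target — has a closed form, and the recommended application mode of the
test (rule-in: a positive call justifies surgery; rule-out: a negative call
justifies observation) follows from evaluating both curves at the local
risk of malignancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, UndefinedMetricError

__all__ = [
    "expected_ppv",
    "expected_npv",
    "PrevalenceCurve",
    "npv_crossover",
    "ppv_crossover",
    "ModeRecommendation",
    "recommend_mode",
    "DegenerateOperatingPointWarning",
]


class DegenerateOperatingPointWarning(UserWarning):
    """A perfect sensitivity/specificity makes a crossover trivially degenerate."""


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"{name} must be in [0, 1], got {value}")
    return value


def expected_ppv(sens: float, spec: float, p: float) -> float:
    """PPV at prevalence ``p`` for a test with the given sensitivity/specificity.

    Endpoints are taken as limits: PPV(1) = 1 always; PPV(0) = 0 unless the
    test is perfectly specific, in which case every positive is a true
    positive and the limit is 1.
    """
    sens, spec, p = (_check_unit(n, v) for n, v in
                     (("sens", sens), ("spec", spec), ("p", p)))
    num = sens * p
    den = num + (1.0 - spec) * (1.0 - p)
    if den == 0.0:
        if p == 1.0:
            return 1.0
        if p == 0.0:
            return 1.0 if spec == 1.0 else 0.0
        raise UndefinedMetricError("expected_ppv", f"sens={sens}, spec={spec}, p={p}")
    return num / den


def expected_npv(sens: float, spec: float, p: float) -> float:
    """NPV at prevalence ``p``; NPV(0) = 1, NPV(1) = 0 unless sens = 1."""
    sens, spec, p = (_check_unit(n, v) for n, v in
                     (("sens", sens), ("spec", spec), ("p", p)))
    num = spec * (1.0 - p)
    den = num + (1.0 - sens) * p
    if den == 0.0:
        if p == 0.0:
            return 1.0
        if p == 1.0:
            return 1.0 if sens == 1.0 else 0.0
        raise UndefinedMetricError("expected_npv", f"sens={sens}, spec={spec}, p={p}")
    return num / den


@dataclass(frozen=True)
class PrevalenceCurve:
    """Expected PPV/NPV evaluated on a prevalence grid for one operating point."""

    sens: float
    spec: float
    grid: np.ndarray
    ppv_values: np.ndarray = field(init=False)
    npv_values: np.ndarray = field(init=False)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise DomainError("grid must be a strictly increasing 1-d array")
        if grid[0] < 0.0 or grid[-1] > 1.0:
            raise DomainError("grid must lie in [0, 1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(
            self, "ppv_values",
            np.array([expected_ppv(self.sens, self.spec, p) for p in grid]),
        )
        object.__setattr__(
            self, "npv_values",
            np.array([expected_npv(self.sens, self.spec, p) for p in grid]),
        )

    @classmethod
    def from_operating_point(
        cls, sens: float, spec: float, n_points: int = 1001
    ) -> "PrevalenceCurve":
        return cls(sens=sens, spec=spec, grid=np.linspace(0.0, 1.0, n_points))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"prevalence": self.grid, "ppv": self.ppv_values, "npv": self.npv_values}
        )


def npv_crossover(sens: float, spec: float, target: float) -> float:
    """Highest prevalence at which NPV still meets ``target``.

    Closed form ``p* = (1−t)·spec / ((1−t)·spec + t·(1−sens))``;
    NPV(p) ≥ target iff p ≤ p*.  A perfectly sensitive test has NPV ≡ 1 and
    returns 1 with a degenerate-operating-point warning.
    """
    sens, spec = _check_unit("sens", sens), _check_unit("spec", spec)
    if not (0.0 < target < 1.0):
        raise DomainError(f"target must be in (0, 1), got {target}")
    if sens == 1.0:
        warnings.warn("sens = 1 makes NPV identically 1", DegenerateOperatingPointWarning)
        return 1.0
    num = (1.0 - target) * spec
    return num / (num + target * (1.0 - sens))


def ppv_crossover(sens: float, spec: float, target: float) -> float:
    """Lowest prevalence at which PPV reaches ``target``.

    Closed form ``p* = t·(1−spec) / (t·(1−spec) + (1−t)·sens)``;
    PPV(p) ≥ target iff p ≥ p*.  A perfectly specific test has PPV ≡ 1 for
    any positive prevalence and returns 0 with a warning.
    """
    sens, spec = _check_unit("sens", sens), _check_unit("spec", spec)
    if not (0.0 <= target < 1.0):
        raise DomainError(f"target must be in [0, 1), got {target}")
    if target == 0.0:
        return 0.0
    if spec == 1.0:
        warnings.warn("spec = 1 makes PPV identically 1", DegenerateOperatingPointWarning)
        return 0.0
    num = target * (1.0 - spec)
    return num / (num + (1.0 - target) * sens)


@dataclass(frozen=True)
class ModeRecommendation:
    """Rule-in / rule-out recommendation at a stated risk of malignancy."""

    mode: str  # rule_in | rule_out | both | neither
    rom_used: float
    ppv_at_rom: float
    npv_at_rom: float
    ppv_target: float
    npv_target: float

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "rom_used": self.rom_used,
            "ppv_at_rom": self.ppv_at_rom,
            "npv_at_rom": self.npv_at_rom,
            "ppv_target": self.ppv_target,
            "npv_target": self.npv_target,
        }


def recommend_mode(
    sens: float,
    spec: float,
    rom: float,
    npv_target: float = 0.90,
    ppv_target: float = 0.75,
) -> ModeRecommendation:
    """Evaluate both predictive-value curves at the local ROM and recommend.

    The test qualifies as rule-out when its expected NPV at the operating
    prevalence meets ``npv_target`` (a negative call is safe to observe),
    and as rule-in when expected PPV meets ``ppv_target`` (a positive call
    justifies surgery).  At a 74% risk of malignancy a test with sens 0.88 /
    spec 0.53 is rule-in only; at 20% the same test becomes rule-out.
    """
    ppv = expected_ppv(sens, spec, rom)
    npv = expected_npv(sens, spec, rom)
    rule_in = ppv >= ppv_target
    rule_out = npv >= npv_target
    mode = {
        (True, True): "both",
        (True, False): "rule_in",
        (False, True): "rule_out",
        (False, False): "neither",
    }[(rule_in, rule_out)]
    return ModeRecommendation(
        mode=mode,
        rom_used=float(rom),
        ppv_at_rom=ppv,
        npv_at_rom=npv,
        ppv_target=float(ppv_target),
        npv_target=float(npv_target),
    )
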