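"""Exception hierarchy.

Every failure mode raises a typed exception rather than returning NaN or a
sentinel: silent NaNs corrupt downstream chi-squared comparisons and curve
evaluations, so undefined quantities are loud by design.
"""


class ThyriskError(Exception):
    """Base class for all package errors."""


class AlterationParseError(ThyriskError, ValueError):
    """A molecular-alteration string does not match the accepted grammar."""

    def __init__(self, text: str, reason: str):
        self.text = text
        self.reason = reason
        super().__init__(f"cannot parse alteration {text!r}: {reason}")


class DomainError(ThyriskError, ValueError):
    """A numeric argument is outside its documented domain."""


class ConfigError(ThyriskError, ValueError):
    """A configuration object violates its invariants."""


class CalibrationError(ThyriskError, ValueError):
    """A requested operating point cannot be realised by the score family."""


class UndefinedMetricError(ThyriskError, ZeroDivisionError):
    """A proportion metric has a zero denominator."""

    def __init__(self, metric: str, detail: str = ""):
        self.metric = metric
        msg = f"metric {metric!r} is undefined (zero denominator)"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ContractError(ThyriskError, ValueError):
    """An operation received records violating its preconditions."""


class LoadError(ThyriskError, ValueError):
    """A tabular input file is malformed; carries row/column context."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(message + (f" ({', '.join(loc)})" if loc else ""))
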