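"""Exception hierarchy for thermogate.

All package errors derive from :class:`ThermogateError` so callers can catch
one base class; each analysis stage raises a narrow subclass that names the
failure mode (no steep Arrhenius component, flat melt curve, ...).
"""


class ThermogateError(Exception):
    """Base class for all thermogate errors."""


class DomainError(ThermogateError, ValueError):
    """Input outside the physical domain of an operation (e.g. T <= 0 K)."""


class InsufficientDataError(ThermogateError):
    """Too few usable samples for the requested operation."""


class NoSteepComponentError(ThermogateError):
    """No sliding window of the Arrhenius profile meets the r^2 criterion."""


class NoIntersectionError(ThermogateError):
    """Baseline and steep fits are parallel (or the profile is one line)."""


class NoActivationError(ThermogateError):
    """Leak-subtracted current never rises above zero; no heat activation."""


class MissingReferenceError(ThermogateError):
    """A required reference value (capsaicin current, 20 degC sample) is absent."""


class ExtrapolationError(ThermogateError):
    """Probe temperature outside the recorded temperature range."""


class FitFailureError(ThermogateError):
    """Nonlinear fit failed to converge after all multi-starts."""


class DegenerateDataError(ThermogateError):
    """Data carry no information for the fit (e.g. all responses equal)."""


class FlatCurveError(ThermogateError):
    """Melt curve maximum does not exceed the 20 degC reference fluorescence."""


class UndefinedCorrelationError(ThermogateError):
    """Correlation undefined (constant variable or fewer than 3 pairs)."""


class InsufficientReplicatesError(ThermogateError):
    """A group has fewer than 2 values; SEM and tests are undefined."""


class ParseError(ThermogateError):
    """Malformed input file; message names the offending line/column."""

    def __init__(self, message: str, *, line: int | None = None,
                 column: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.line = line
        self.column = column
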