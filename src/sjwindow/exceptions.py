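"""Exception hierarchy shared across the package.

``SJWindowError`` is the common base so callers can catch everything the
package raises with one clause; the CLI maps ``ValidationError`` subtypes to
exit code 1 and everything else to exit code 2.
"""


class SJWindowError(Exception):
    """Base class for all package errors."""


class ValidationError(SJWindowError, ValueError):
    """Invalid user input: specs, configs, or malformed data files."""


class InfeasibleSOAError(ValidationError):
    """Requested SOA magnitude exceeds what the delay range can realize."""


class DelayRangeError(ValidationError):
    """Leading delay outside the feasible interval for the requested SOA."""


class InsufficientDataError(SJWindowError):
    """Too few trials / SOA levels / participants for the requested analysis."""


class FitFailureError(SJWindowError):
    """Psychometric fit did not converge even after penalization."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoCrossingError(SJWindowError):
    """Fitted slope too shallow for a usable 50% crossing on this side."""


class DegenerateDifferencesError(SJWindowError):
    """Paired differences have zero variance but a nonzero mean: t is infinite."""
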