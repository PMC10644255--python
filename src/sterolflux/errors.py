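"""Exception hierarchy.

All package errors derive from :class:`SterolFluxError` so callers can catch
one base class; the CLI maps each subclass to a distinct exit code.
"""


class SterolFluxError(Exception):
    """Base class for all sterolflux errors."""


class ParameterError(SterolFluxError, ValueError):
    """Invalid kinetic parameter or state (e.g. negative rate constant)."""


class SingularityError(SterolFluxError, ZeroDivisionError):
    """A required rate constant is zero where a closed form divides by it."""


class IntegrationError(SterolFluxError, RuntimeError):
    """The ODE solver failed; carries solver diagnostics in the message."""


class ParseError(SterolFluxError, ValueError):
    """Malformed time-course CSV input."""


class NonIdentifiableError(SterolFluxError, ValueError):
    """Degenerate data from which the requested parameters cannot be inferred."""


class DegenerateFitError(SterolFluxError, ValueError):
    """A fit statistic is undefined (e.g. information criteria at RSS = 0)."""
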