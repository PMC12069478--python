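"""Exception hierarchy.

All errors raised by the library derive from :class:`HypertabError`, so callers
can catch a single base class. The distinction that matters operationally is
between unrecoverable configuration problems (bad tables, missing fibers) and
:class:`DomainError`, which is recoverable: a driver that hits a logarithm
domain violation cuts its step size and retries.
"""

from __future__ import annotations


class HypertabError(Exception):
    """Base class for all library errors."""


class InvalidDeformationError(HypertabError):
    """Deformation gradient is not admissible (det F <= 0 or non-finite)."""


class ConfigurationError(HypertabError):
    """Model references invariant slots or mixed ids that are not available."""


class SelectorError(HypertabError):
    """Unknown activation-function selector or invalid power."""


class DomainError(HypertabError):
    """Argument left the admissible domain of a logarithmic activation.

    Carries the offending argument value so drivers can report it when they
    cut the step.
    """

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class ParseError(HypertabError):
    """Malformed parameter-table text; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class CatalogError(HypertabError):
    """Unknown catalog model name."""


class SolverError(HypertabError):
    """Newton iteration on a lateral-traction condition failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
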