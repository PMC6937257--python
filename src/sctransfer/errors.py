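"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2 (click),
:class:`DataValidationError` -> 3, :class:`NumericalError` -> 4.
"""


class SCTransferError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(SCTransferError, ValueError):
    """Malformed, inconsistent or out-of-domain input data."""


class EmptyResultError(DataValidationError):
    """A filter or intersection removed every gene or cell."""


class NumericalError(SCTransferError, RuntimeError):
    """A numerical routine failed (degenerate eigenproblem, no valid fit...)."""
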