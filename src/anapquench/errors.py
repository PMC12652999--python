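"""Structured exceptions.

The CLI maps these onto process exit codes: validation problems exit 2,
data problems exit 3, fit failures exit 4.
"""


class AnapQuenchError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(AnapQuenchError):
    """Invalid parameters or configuration (bad bandwidth, malformed config...)."""

    exit_code = 2


class DataError(AnapQuenchError):
    """Input data violates a contract (nonpositive fluorescence, empty band...)."""

    exit_code = 3


class GridMismatchError(DataError):
    """Two objects that must share a wavelength/time grid do not."""


class CoverageError(DataError):
    """A spectrum does not cover the wavelength range required by an operation."""


class FitError(AnapQuenchError):
    """An optimizer failed to converge or produced a degenerate result."""

    exit_code = 4

    def __init__(self, *args, last_fit=None):
        super().__init__(*args)
        self.last_fit = last_fit
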