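"""Exception hierarchy.

ValidationError maps to CLI exit code 2, InsufficientDataError to exit code 3.
"""

from __future__ import annotations


class BddError(Exception):
    """Base class for all package errors."""


class ValidationError(BddError):
    """Malformed or out-of-contract input."""


class InsufficientDataError(BddError):
    """Structurally valid input with too few observations to proceed."""


class ConstantSeriesError(ValidationError):
    """Pearson correlation requested on a zero-variance series."""
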