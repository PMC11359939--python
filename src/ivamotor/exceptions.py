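"""Exception hierarchy used across the package."""


class IvamotorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IvamotorError, ValueError):
    """A file or container violates the expected layout."""


class DataError(IvamotorError, ValueError):
    """Input data violate a numerical precondition (non-finite, rank-deficient, ...)."""


class ConvergenceError(IvamotorError, RuntimeError):
    """An iterative fit diverged (NaN/inf cost)."""
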