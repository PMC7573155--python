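"""Exception types raised across the package."""


class FcresponseError(Exception):
    """Base class for package errors."""


class InvalidSpecError(FcresponseError, ValueError):
    """A synthetic-data or run specification violates its invariants."""


class SingularMatrixError(FcresponseError):
    """A correlation/design matrix is singular where an inverse is required."""


class DegenerateDataError(FcresponseError, ValueError):
    """Input data are degenerate for the requested computation."""
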