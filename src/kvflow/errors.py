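"""Exception hierarchy shared across the package."""


class KvflowError(Exception):
    """Base class for all package-specific errors."""


class DimensionMismatchError(KvflowError, ValueError):
    """Two inputs that must share a shape/category structure do not."""


class DomainError(KvflowError, ValueError):
    """A numeric argument lies outside its mathematically valid domain."""


class ParameterError(KvflowError, ValueError):
    """A configuration parameter is invalid (e.g. non-positive resample count)."""


class ReconstructionError(KvflowError, ValueError):
    """No integer count vector is consistent with printed percentages.

    Carries ``near_misses``: a list of ``(total, counts, max_deviation)``
    tuples for the closest candidates, to aid diagnosis.
    """

    def __init__(self, message: str, near_misses=None):
        super().__init__(message)
        self.near_misses = list(near_misses or [])


class DegenerateTableError(KvflowError, ValueError):
    """A 2x2 table has a zero margin, so the exact test is undefined."""


class EmptyResultError(KvflowError, ValueError):
    """A filter left no eligible data (e.g. no track in the duration window)."""


class ParseError(KvflowError, ValueError):
    """A data file violates the expected on-disk format."""
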