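"""Exception hierarchy shared across the package."""


class FuncmotifError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FuncmotifError, ValueError):
    """Input data violates a container invariant (negative count, duplicate id, ...)."""


class ParseError(FuncmotifError, ValueError):
    """A tabular file could not be interpreted (non-numeric cell, bad header, ...)."""


class AlignmentError(FuncmotifError, ValueError):
    """Sample identifiers do not match between companion tables."""


class ParameterError(FuncmotifError, ValueError):
    """A function argument is outside its documented domain."""


class SegmentationError(FuncmotifError, ValueError):
    """A family has too few presences for the requested number of abundance classes."""


class DegreesOfFreedomError(FuncmotifError, ValueError):
    """Model requires n > p + 1 observations (or n - k - 1 > 0 for the AICc)."""


class DegeneratePropertyError(FuncmotifError, ValueError):
    """The response has zero variance, so no variance-explained measure exists."""


class GenerationError(FuncmotifError, ValueError):
    """The synthetic-truth object cannot produce a value for a realized motif."""
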