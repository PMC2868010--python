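"""Exception hierarchy.

All errors raised by the library derive from :class:`DfmAlignError`, so
callers (and the CLI) can distinguish input/validation problems from
runtime failures.
"""


class DfmAlignError(Exception):
    """Base class for all dfmalign errors."""


class ValidationError(DfmAlignError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file could not be parsed in any supported format."""


class SizeError(DfmAlignError):
    """Instance too large for the requested (exhaustive) operation."""


class DegenerateSampleError(DfmAlignError):
    """A statistical fit was requested on a degenerate sample."""


class CalibrationError(DfmAlignError):
    """Null-model calibration failed (e.g. an underpopulated score bin)."""


class ModelRangeError(DfmAlignError):
    """An EVD model was evaluated where its scale is non-positive."""
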