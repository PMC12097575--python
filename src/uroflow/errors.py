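"""Exception hierarchy.

Exit-code convention used by the CLI: 2 validation, 3 I/O, 4 numeric.
"""


class UroflowError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(UroflowError):
    """Input violates a documented precondition or enumeration."""

    exit_code = 2


class ChannelMappingError(ValidationError):
    """A required channel/feature cannot be located in the input."""


class FormatError(UroflowError):
    """Unreadable, truncated or unwritable file."""

    exit_code = 3


class InsufficientControlError(ValidationError):
    """Too few positive events in a single-stain control."""


class NonPhysicalSpilloverError(ValidationError):
    """Estimated off-diagonal spillover coefficient >= 1."""


class NumericError(UroflowError):
    """Singular matrix or other numerical failure."""

    exit_code = 4


class EmptySampleError(ValidationError):
    """A sample with zero non-bead events cannot be summarized."""


class DegenerateDataError(ValidationError):
    """Statistical test input carries no variance at all."""
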