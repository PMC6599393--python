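"""Exception hierarchy shared across the package."""


class StateDynError(Exception):
    """Base class for all package errors."""


class FormatError(StateDynError):
    """Malformed input file (ragged rows, bad structure)."""


class ParseError(StateDynError):
    """Unparseable cell or token, with coordinates."""


class DegenerateInputError(StateDynError):
    """Input too small or trivial for the requested operation."""


class ConstantChannelError(StateDynError):
    """A channel with zero variance where scaling is required."""


class ValidationError(StateDynError):
    """Invalid configuration or domain-object state."""


class DesignError(StateDynError):
    """Statistical design cannot be estimated (empty cell, K too small)."""


class NumericalError(StateDynError):
    """Non-finite quantity encountered during inference."""


class AlignmentError(StateDynError):
    """State alignment prerequisites not met (invalid assignment, bad k)."""
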