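"""Exception hierarchy shared by all stages."""


class SpatDivError(Exception):
    """Base class for all package errors."""


class FormatError(SpatDivError):
    """An input file does not conform to its expected format."""


class EmptyInputError(SpatDivError):
    """An input is empty where content is required."""


class ValidationError(SpatDivError):
    """Input content violates a domain invariant."""


class AlignmentError(SpatDivError):
    """Occurrence matrix, tree and traits cannot be reconciled."""


class ConfigError(SpatDivError):
    """A configuration value is invalid."""
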