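"""Exception hierarchy shared across the pipeline stages."""


class ArtfeatError(Exception):
    """Base class for package errors."""


class ParameterError(ArtfeatError, ValueError):
    """Invalid parameter or specification value."""


class FormatError(ArtfeatError, ValueError):
    """Unreadable or unsupported file format."""


class PreconditionError(ArtfeatError, ValueError):
    """Operation called on inputs violating its contract."""


class DegenerateInputError(ArtfeatError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. silence)."""


class ConfigError(ArtfeatError, ValueError):
    """Invalid analysis configuration."""
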