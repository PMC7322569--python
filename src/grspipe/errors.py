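"""Exception hierarchy shared across the pipeline."""


class GrsPipeError(Exception):
    """Base class for all package errors."""


class ConfigError(GrsPipeError):
    """Invalid configuration value; message names the offending field."""


class FormatError(GrsPipeError):
    """A file does not conform to its on-disk format."""


class SchemaError(GrsPipeError):
    """A table is missing required columns."""


class ValidationError(GrsPipeError):
    """A record violates a domain invariant."""


class ComputationError(GrsPipeError):
    """A statistical computation cannot be carried out on the given input."""
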