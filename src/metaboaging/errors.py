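"""Exception hierarchy shared across the pipeline."""


class MetaboagingError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetaboagingError):
    """Invalid generator or pipeline configuration; message names the field."""


class DataError(MetaboagingError):
    """Input data violates a precondition (degenerate, singular, out of range)."""


class MissingInputError(MetaboagingError):
    """A pipeline stage's required upstream output is absent."""
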