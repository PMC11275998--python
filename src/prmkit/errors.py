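"""Exception hierarchy shared across prmkit modules."""


class PrmkitError(Exception):
    """Base class for all prmkit errors."""


class SchemaError(PrmkitError):
    """A tabular input is missing required columns or has the wrong layout."""


class ValidationError(PrmkitError):
    """A value in an input violates its domain invariants."""


class DuplicateKeyError(ValidationError):
    """Two records share a key that must be unique."""


class InsufficientDataError(PrmkitError):
    """Not enough data points to perform the requested estimate."""
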