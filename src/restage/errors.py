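"""Exception hierarchy shared by all pipeline stages."""


class RestageError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(RestageError):
    """A table is missing a required column or has an unreadable header."""


class ValidationError(RestageError):
    """A record violates a domain invariant (duplicate id, negative absorbance...)."""


class ParseError(RestageError):
    """A cell could not be converted to its declared type."""


class PairingError(RestageError):
    """A sample lacks the target or reference Ct measurement needed for ddCt."""


class ComputationError(RestageError):
    """A quantity is undefined for the given inputs (no vehicle wells, zero mean...)."""


class DegenerateVarianceError(ComputationError):
    """Paired differences have zero spread; the t statistic is undefined."""
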