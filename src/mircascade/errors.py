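"""Exception hierarchy shared across the pipeline."""


class MircascadeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MircascadeError):
    """A file violates the expected tabular dialect (columns, duplicates)."""


class ValidationError(MircascadeError):
    """Parsed content violates a domain invariant (range, enum, sign)."""


class DegenerateInputError(MircascadeError):
    """A statistical routine received input it cannot test (e.g. n < 2)."""


class ConfigurationError(MircascadeError):
    """The requested run cannot proceed with the supplied configuration."""
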