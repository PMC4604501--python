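"""Package-wide exception types."""


class SerscalError(Exception):
    """Base class for errors raised by serscal."""


class DegenerateInputError(SerscalError, ValueError):
    """Input is structurally valid but statistically degenerate.

    Raised e.g. for a constant spectrum handed to SNV (zero standard
    deviation) or constant regression targets (zero variance).
    """


class FormatError(SerscalError, ValueError):
    """A file does not conform to the expected text format."""
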