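"""Exception hierarchy for palinmito."""


class PalinmitoError(Exception):
    """Base class for all palinmito errors."""


class ParameterError(PalinmitoError, ValueError):
    """An operation was configured with an invalid parameter value."""


class InputError(PalinmitoError, ValueError):
    """Inputs are structurally valid but inconsistent with each other
    (e.g. an architecture applied to a different contig)."""


class ParseError(PalinmitoError, ValueError):
    """A file could not be parsed as the declared format."""
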