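"""Exception hierarchy."""


class MethgetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MethgetError):
    """A file does not conform to its declared format."""


class DataError(MethgetError):
    """Inputs are well-formed but inconsistent or insufficient."""
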