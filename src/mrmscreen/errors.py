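"""Exception hierarchy shared across the package."""


class MrmScreenError(Exception):
    """Base class for all package errors."""


class ParseError(MrmScreenError):
    """A file could not be parsed in the requested dialect."""


class NonMonotoneRTError(ParseError):
    """Retention-time axis is not strictly increasing."""


class LengthMismatchError(ParseError):
    """rt and intensity columns differ in length."""


class GridMismatchError(MrmScreenError):
    """Two traces expected on one retention-time grid do not share it."""


class ConfigError(MrmScreenError):
    """Invalid or incomplete configuration."""
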