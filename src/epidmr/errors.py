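"""Exception hierarchy shared across the package."""


class EpidmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpidmrError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(EpidmrError, ValueError):
    """Malformed or out-of-contract input data."""


class InsufficientDataError(EpidmrError, ValueError):
    """Not enough observations to compute the requested quantity."""


class ParseError(EpidmrError, ValueError):
    """A text table could not be parsed; message names the offending cell."""
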