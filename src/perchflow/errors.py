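"""Exception hierarchy.

``ValidationError`` covers bad parameters and malformed requests (CLI exit
code 2); the remaining errors are data-processing failures (exit code 1).
"""


class PerchflowError(Exception):
    """Base class for all perchflow errors."""


class ValidationError(PerchflowError):
    """Invalid parameters, missing columns, or malformed configuration."""


class TimeSpecError(ValidationError):
    """A timestamp order specification is malformed."""


class ParseError(PerchflowError):
    """A data value (timestamp, coordinate, raw line) could not be parsed."""


class ImpossibleReadError(PerchflowError):
    """The same animal was read at two different loggers within the visit cutoff."""
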