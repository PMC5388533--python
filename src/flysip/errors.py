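"""Exception hierarchy shared across flysip modules."""


class FlysipError(Exception):
    """Base class for all flysip errors."""


class ParameterError(FlysipError, ValueError):
    """An argument or configuration field is invalid; the message names the field."""


class FormatError(FlysipError, ValueError):
    """An input file does not conform to the expected layout."""


class DataError(FlysipError, ValueError):
    """A record carries a physically impossible or inconsistent value."""


class UsageError(FlysipError, RuntimeError):
    """An operation was called on data that its contract excludes."""


class InsufficientBaselineError(FlysipError, ValueError):
    """Too few usable pre-stimulus frames to estimate baseline fluorescence."""


class DegenerateFitError(FlysipError, ValueError):
    """A regression or calibration fit has no unique solution."""
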