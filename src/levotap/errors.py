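"""Exception types used across the package."""


class LevotapError(Exception):
    """Base class for package errors."""


class InvalidParameterError(LevotapError, ValueError):
    """A model parameter is outside its admissible domain."""


class InputError(LevotapError, ValueError):
    """Malformed input data (series, files, arguments)."""


class DegenerateDataError(InputError):
    """Data carry no usable signal (e.g. all-zero observations)."""


class FormatError(InputError):
    """A file does not follow the expected dialect."""


class CalibrationError(LevotapError, RuntimeError):
    """Network calibration could not satisfy its constraints."""
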