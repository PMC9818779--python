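"""Exception hierarchy for cocoanir.

All package errors derive from :class:`CocoaNIRError` so callers can catch
one base class; subclasses distinguish configuration, grid/data and model
serialization problems (the CLI maps them onto distinct exit codes).
"""


class CocoaNIRError(Exception):
    """Base class for all cocoanir errors."""


class ConfigError(CocoaNIRError):
    """Invalid configuration or parameter combination."""


class GridError(CocoaNIRError):
    """Wavelength grid mismatch or off-grid request."""


class DataValidationError(CocoaNIRError):
    """Malformed dataset: duplicate ids, missing cells, bad shapes."""


class ModelIOError(CocoaNIRError):
    """Model file cannot be parsed or has an incompatible schema version."""


class DegenerateDataError(CocoaNIRError):
    """Data admit no meaningful fit (zero variance, all samples flagged...)."""
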