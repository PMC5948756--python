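"""Exception hierarchy shared by all pipeline stages."""


class CSFCountError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(CSFCountError):
    """A configuration document could not be read or contained unknown keys."""


class ValidationError(ConfigError):
    """A parameter violated a type invariant.

    Carries the offending field name so callers can point the user at it.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InputError(CSFCountError):
    """Missing, unreadable, or unpairable input files."""


class MeasurementError(CSFCountError):
    """A quantity could not be measured (e.g. SNR with no detections)."""


class SedimentationError(CSFCountError):
    """Settling velocity is non-positive, so cells never reach the floor."""
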