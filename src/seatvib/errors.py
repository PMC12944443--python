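"""Exception taxonomy shared across the pipeline."""


class SeatvibError(Exception):
    """Base class for all package errors."""


class ConfigError(SeatvibError):
    """A configuration value violates its contract (ranges, ordering)."""


class CalibrationError(SeatvibError):
    """Extrinsic calibration is invalid (non-orthonormal rotation, ...)."""


class SessionFormatError(SeatvibError):
    """A session file is structurally malformed (missing columns, ...)."""


class SessionDataError(SeatvibError):
    """Session content violates a data invariant (non-monotone time, ...)."""


class ContractError(SeatvibError):
    """An operation was called with inputs that break its precondition."""
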