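"""Exception hierarchy shared across the pipeline stages."""


class WavecohError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(WavecohError, ValueError):
    """A trial or run specification violates its invariants."""


class ConfigError(WavecohError, ValueError):
    """A stage configuration is internally inconsistent or out of range."""


class TriggerError(WavecohError, ValueError):
    """Trial triggers are missing or ill-ordered (t3 <= t2)."""


class InsufficientDurationError(WavecohError, ValueError):
    """A trial is too short for the requested operation (< 3 s minimum)."""


class MappingError(WavecohError, KeyError):
    """A region map references channels absent from the record."""


class PairingError(WavecohError, ValueError):
    """Signal pairing cannot be constructed (duplicates, single trial, ...)."""


class DegenerateDataError(WavecohError, ValueError):
    """Data are degenerate for the requested statistic (zero variance, ...)."""
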