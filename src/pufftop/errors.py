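"""Exception hierarchy for the pufftop pipeline."""


class PuffTopError(Exception):
    """Base class for all pufftop errors."""


class FormatError(PuffTopError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ParseError(PuffTopError):
    """A cell could not be parsed; carries the offending 1-based data row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(PuffTopError):
    """Data violate a stream invariant (ordering, overlap, range)."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ConfigurationError(PuffTopError):
    """A configuration object or scenario is internally inconsistent."""


class UndefinedThresholdError(PuffTopError):
    """A participant has no usable interpuff intervals, so the adaptive
    session threshold (their mean IPI) is undefined."""
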