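"""Typed errors raised across the package."""


class BarfitError(Exception):
    """Base class for all package errors."""


class SchemaError(BarfitError):
    """A tabular input is missing required columns."""


class ValidationError(BarfitError):
    """A record violates an invariant (bad alphabet, duplicate key, ...)."""


class ParameterError(BarfitError):
    """A caller-supplied parameter is outside its allowed range."""


class FastqParseError(BarfitError):
    """A FASTQ stream is malformed; carries the failing record number."""

    def __init__(self, message: str, record_number: int | None = None):
        super().__init__(message)
        self.record_number = record_number


class StageError(BarfitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
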