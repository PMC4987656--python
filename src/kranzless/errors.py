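"""Exception hierarchy shared across the pipeline."""


class KranzlessError(Exception):
    """Base class for all package errors."""


class ConfigError(KranzlessError):
    """A configuration value is missing, unknown, or out of range."""


class ParseError(KranzlessError):
    """An input file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StitchError(KranzlessError):
    """A fragment join failed validation (identity below threshold, missing id)."""


class StageError(KranzlessError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
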