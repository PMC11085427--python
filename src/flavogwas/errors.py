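"""Exception hierarchy shared across the pipeline stages."""


class FlavogwasError(Exception):
    """Base class for all package errors."""


class InvalidSymbolError(FlavogwasError, ValueError):
    """A gene symbol is empty or otherwise unusable."""


class FormatError(FlavogwasError, ValueError):
    """An input file does not conform to its expected layout."""


class UsageError(FlavogwasError, ValueError):
    """An operation was called with arguments outside its contract."""


class ConfigError(FlavogwasError, ValueError):
    """A run configuration failed validation (CLI exit code 2)."""


class StageError(FlavogwasError, RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
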