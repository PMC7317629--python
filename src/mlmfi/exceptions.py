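"""Exception hierarchy shared across the package."""


class MlmfiError(Exception):
    """Base class for all package errors."""


class ConfigError(MlmfiError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(MlmfiError):
    """Input file does not conform to the documented dialect."""


class DataError(MlmfiError):
    """Semantically invalid data (e.g. event date before follow-up start)."""


class DegenerateOutcomeError(MlmfiError):
    """Classification target has fewer than two classes."""


class PipelineError(MlmfiError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
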