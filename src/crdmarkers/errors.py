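"""Exception hierarchy shared across the pipeline.

Exit-code convention for the CLI: 2 = configuration error, 3 = data error,
4 = stage failure inside the orchestrated pipeline.
"""


class ConfigError(ValueError):
    """Invalid configuration (unknown key, out-of-range threshold, ...)."""

    exit_code = 2


class DataError(ValueError):
    """Structurally invalid or insufficient input data."""

    exit_code = 3


class InsufficientDataError(DataError):
    """Too few observations for the requested fit or test."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    exit_code = 4

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
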