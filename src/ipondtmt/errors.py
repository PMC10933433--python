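"""Exception hierarchy shared across the pipeline.

``ConfigError`` (and its subclasses) signal user-input problems and map to
exit code 1 on the command line; anything else is a runtime failure (exit 2).
"""


class IpondError(Exception):
    """Base class for all package errors."""


class ConfigError(IpondError, ValueError):
    """Invalid configuration: bad thresholds, unknown sets/levels, etc."""


class FormatError(ConfigError):
    """A file does not follow the expected dialect (missing column, bad line)."""


class DesignMismatchError(ConfigError):
    """Sample design and quantification table disagree."""


class DataError(IpondError):
    """Values violate a data contract (e.g. non-positive raw intensity)."""


class ValidationError(ConfigError):
    """Numeric argument outside its legal domain."""


class PipelineError(IpondError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
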