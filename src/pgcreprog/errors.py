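"""Exception types shared across the package."""


class PgcReprogError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(PgcReprogError, ValueError):
    """An invalid configuration value or combination."""


class SizingError(ConfigurationError):
    """A chromosome cannot host the requested features."""


class ParseError(PgcReprogError, ValueError):
    """A malformed input file.

    Carries the 1-based line number of the first offending line when known.
    """

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PipelineStageError(PgcReprogError, RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
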