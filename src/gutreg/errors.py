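"""Exception hierarchy shared across the package."""


class GutregError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GutregError, ValueError):
    """A file could not be parsed; message names the offending line."""


class SchemaError(GutregError, ValueError):
    """A table is missing required columns or carries unexpected samples."""


class NormalizationError(GutregError, ValueError):
    """Size-factor normalization is undefined for the given matrix."""


class DegenerateDataError(GutregError, ValueError):
    """A statistical routine received data it cannot fit."""


class CapacityError(GutregError, ValueError):
    """A simulated genome is too small for the requested layout."""


class StageError(GutregError, RuntimeError):
    """A pipeline stage failed; carries the stage name and root cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
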