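"""Exception hierarchy for retseg."""


class RetsegError(Exception):
    """Base class for all retseg errors."""


class FormatError(RetsegError):
    """Raster file exists but cannot be interpreted (channel count, encoding)."""


class DegenerateMaskError(RetsegError):
    """A field-of-view mask contains no true pixel."""


class DegenerateImageError(RetsegError):
    """An image is constant where a spread of intensities is required."""


class DegenerateSpecError(RetsegError):
    """A phantom specification produces no usable content."""


class ParameterError(RetsegError, ValueError):
    """A parameter violates its documented domain."""


class NumericalError(RetsegError, RuntimeError):
    """An iterative scheme produced non-finite values."""


class StageError(RetsegError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
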