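"""Exception hierarchy shared across the package."""


class MsiFluxError(Exception):
    """Base class for all package errors."""


class FormatError(MsiFluxError, ValueError):
    """A file does not conform to the expected dialect."""


class EmptyImageError(MsiFluxError, ValueError):
    """An operation would leave no pixels."""


class EmptySelectionError(MsiFluxError, ValueError):
    """A feature filter removed every feature."""


class NotNormalizedError(MsiFluxError, RuntimeError):
    """An operation requires (or forbids) TIC-normalized input."""


class InfeasibleRatioError(MsiFluxError, ValueError):
    """A flux-ratio set implies an isotopologue enrichment outside (0, 1)."""


class StageError(MsiFluxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
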