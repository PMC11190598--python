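"""Exception hierarchy shared across the pipeline stages."""


class EmghhtError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EmghhtError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(EmghhtError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class DegenerateSignalError(EmghhtError, ValueError):
    """A signal has too few extrema to support envelope construction."""


class DivergedTrainingError(EmghhtError, RuntimeError):
    """Training produced a non-finite loss; the message names the learning rate."""


class PipelineStageError(EmghhtError, RuntimeError):
    """A pipeline stage failed; carries the stage name and input identifier."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")
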