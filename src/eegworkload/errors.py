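"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A domain invariant was violated.

    Parameters
    ----------
    invariant : str
        Short machine-readable name of the violated invariant.
    message : str
        Human-readable description.
    """

    def __init__(self, invariant: str, message: str):
        self.invariant = invariant
        super().__init__(f"[{invariant}] {message}")


class ParseError(ValueError):
    """A file could not be parsed. Carries the byte offset where parsing failed."""

    def __init__(self, message: str, byte_offset: int | None = None):
        self.byte_offset = byte_offset
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)


class UnitError(ValueError):
    """A physical unit outside the supported volt family was encountered."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
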