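"""Exception hierarchy shared across the pipeline."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetpharmError):
    """A file violates the expected dialect or its values fail validation."""


class ValidationError(NetpharmError):
    """An in-memory object violates a domain invariant."""


class EmptyResultError(NetpharmError):
    """An operation produced an empty result the downstream pipeline cannot use."""


class ConvergenceError(NetpharmError):
    """An iterative numerical routine failed to converge."""


class StageError(NetpharmError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
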