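"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input object or parameter violates a documented contract."""


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a result from the given data."""


class PipelineError(RuntimeError):
    """A pipeline stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
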