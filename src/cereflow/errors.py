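"""Exception hierarchy."""


class CereflowError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(CereflowError, ValueError):
    """An image does not have the expected number of dimensions."""


class ValidationError(CereflowError, ValueError):
    """A record or parameter violates a domain invariant."""


class DegenerateCurveError(CereflowError, ValueError):
    """A signal curve has no usable variance (flat curve)."""


class PipelineError(CereflowError, RuntimeError):
    """A stage of the end-to-end analysis failed.

    Attributes
    ----------
    stage : str
        Name of the pipeline stage that failed.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
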