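"""Exception types shared across the pipeline stages."""


class FpannetError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(FpannetError):
    """Input data are degenerate (zero variance, constant residuals, ...)."""


class DisconnectedGraphError(FpannetError):
    """A graph operation that requires connectivity received a disconnected graph."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components or []


class EmptyRoiError(FpannetError):
    """An ROI sphere contains no voxels of the image grid."""


class ValidationError(FpannetError):
    """A run configuration or input layout failed validation."""
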