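"""Exception hierarchy shared across the pipeline stages."""


class FmridxError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(FmridxError):
    """An input object or parameter violates a stated invariant."""


class ConfigError(ValidationError):
    """A run configuration failed schema validation."""


class InsufficientDurationError(FmridxError):
    """A scan is too short for the requested temporal standardization."""


class DegenerateInputError(FmridxError):
    """A statistic needed by an operation is degenerate (zero variance etc.)."""


class PipelineOrderError(FmridxError):
    """Stages invoked out of the supported order (e.g. masking before
    signal normalization, which is known to hurt downstream accuracy)."""


class EmptyMaskError(FmridxError):
    """A brain mask excluded every voxel."""


class GridMismatchError(FmridxError):
    """Two objects that must share a spatial grid do not."""
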