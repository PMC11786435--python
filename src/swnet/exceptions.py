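"""Package-wide exception types."""


class SWNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SWNetError):
    """Invalid build, training, or generator configuration."""


class AuditError(SWNetError):
    """A structural audit could not be resolved (e.g. missing channel info)."""


class ShapeError(SWNetError):
    """Incompatible tensor shapes in the layer graph."""


class EmptyDatasetError(SWNetError):
    """A dataset root or manifest contained no usable records."""


class UnmappedCodeError(SWNetError):
    """A diagnosis code outside the supported benign/malignant mapping."""


class StratificationError(SWNetError):
    """A class has too few records for a stratified split."""


class DivergenceError(SWNetError):
    """Training produced a non-finite loss."""
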