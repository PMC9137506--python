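"""Exception types shared across the pipeline."""


class PermboldError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PermboldError, ValueError):
    """Invalid task, cohort, or study configuration."""


class MaskError(PermboldError, ValueError):
    """Brain-mask computation produced an unusable mask."""


class UndefinedStatisticError(PermboldError, ArithmeticError):
    """The contrast statistic is undefined (zero residual variance or
    zero contrast variance) at the requested voxel."""


class EmptySelectionError(PermboldError, ValueError):
    """A selection step (e.g. significant voxels) returned nothing."""
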