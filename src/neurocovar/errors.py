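"""Exception hierarchy shared across the package."""


class NeurocovarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeurocovarError):
    """A file could not be read as the expected format."""


class GridError(NeurocovarError):
    """Volumes/masks entering one analysis do not share a grid."""


class EmptyROIError(NeurocovarError):
    """A mask or mask intersection contains no voxels."""


class PartitionError(EmptyROIError):
    """An inside/outside partition of the analysis mask is degenerate."""


class NormalizationError(NeurocovarError):
    """A normalization denominator is zero or non-positive."""


class DomainError(NeurocovarError):
    """An input value is outside the operation's domain."""


class DesignError(NeurocovarError):
    """A design matrix is rank deficient or otherwise unusable."""


class SampleSizeError(DesignError):
    """Too few subjects for the requested model."""


class InsufficientPermutationsError(NeurocovarError):
    """Too few permutations to resolve the requested FWE level."""


class GeometryError(NeurocovarError):
    """A synthetic geometry does not fit on the working grid."""


class ConfigurationError(NeurocovarError):
    """A pipeline or analysis configuration is incomplete or inconsistent."""


class CompletenessError(NeurocovarError):
    """Required per-subject inputs are missing."""


class FitError(NeurocovarError):
    """A statistical model failed to converge."""


class RatioError(NormalizationError):
    """A within/outside ratio has a zero denominator."""
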