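"""Exception hierarchy shared across the package."""


class TracermapError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(TracermapError, ValueError):
    """Input array does not have the expected number of dimensions/channels."""


class DomainError(TracermapError, ValueError):
    """Value outside the mathematical domain of an operation (e.g. negative OD)."""


class SingularMatrixError(TracermapError, ValueError):
    """A stain matrix or affine that must be invertible is (near-)singular."""


class ConfigurationError(TracermapError, ValueError):
    """Inconsistent or incomplete detection/anchoring configuration."""


class DegenerateHistogramError(TracermapError, ValueError):
    """Automatic thresholding attempted on an image with a degenerate histogram."""
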