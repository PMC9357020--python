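"""Exception types shared across the package."""


class ConglobeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ConglobeError):
    """A file could not be parsed or violates its declared structure."""


class ShapeMismatchError(ConglobeError):
    """Landmark configurations with incompatible point counts."""


class DegenerateInputError(ConglobeError):
    """Input is geometrically or statistically degenerate (zero size, zero length...)."""


class ConvergenceError(ConglobeError):
    """An iterative procedure failed to converge within its iteration budget."""


class InsufficientDataError(ConglobeError):
    """Too few specimens, nodes or samples for the requested statistic."""


class MappingError(ConglobeError):
    """Taxa, tips or specimens could not be matched between two structures."""


class DimensionalityError(ConglobeError):
    """A covariance subspace is singular or the requested dimension is infeasible."""


class InfeasibleRecordError(ConglobeError):
    """A measurement record is physically impossible (e.g. indenter-dominated compliance)."""
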