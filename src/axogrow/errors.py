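"""Exception hierarchy for axogrow."""


class AxogrowError(Exception):
    """Base class for all axogrow-specific errors."""


class InvalidParameterError(AxogrowError, ValueError):
    """A model or configuration parameter is outside its valid range."""


class GeometryError(AxogrowError, ValueError):
    """A point violates a geometric precondition (e.g. off the circumference)."""


class SingularForceError(AxogrowError, ArithmeticError):
    """The force field was evaluated within tolerance of a node center."""


class DensityError(AxogrowError, ValueError):
    """A network is too sparse to be thresholded to the requested density."""


class DegenerateSampleError(AxogrowError, ValueError):
    """A sample is degenerate (constant, too small, or out of domain) for fitting."""


class ConfigError(AxogrowError, ValueError):
    """A structured pipeline configuration is invalid; message names the field."""


class FitInfeasibleError(AxogrowError, RuntimeError):
    """Every grid cell was excluded (density floor) so no optimum exists."""
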