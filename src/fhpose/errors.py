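"""Exception hierarchy shared across the package."""


class FhposeError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(FhposeError, ValueError):
    """An array does not have the expected shape."""


class ValidationError(FhposeError, ValueError):
    """An argument violates a documented precondition."""


class DegeneratePoseError(FhposeError, ValueError):
    """A pose is geometrically degenerate (e.g. coincident landmarks)."""


class DegenerateInputError(FhposeError, ValueError):
    """Numerical input is degenerate (e.g. rank-0 covariance)."""


class FormatError(FhposeError, ValueError):
    """A file does not conform to the documented on-disk format."""


class TrainingError(FhposeError, RuntimeError):
    """Optimization failed (e.g. loss diverged to NaN)."""


class ContractError(FhposeError, ValueError):
    """A model does not honour a structural contract (e.g. 64-unit penultimate layer)."""
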