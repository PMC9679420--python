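"""Exception hierarchy shared across the package."""


class BspmError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BspmError, ValueError):
    """A numeric or structural parameter is outside its valid domain."""


class ConfigurationError(BspmError):
    """Required channels, weights or settings are missing or inconsistent."""


class GeometryError(BspmError):
    """The torso geometry cannot host the requested construction."""


class DataError(BspmError):
    """Input data violates a contract (NaN, wrong range, wrong shape)."""


class ShapeError(DataError):
    """Array shapes do not line up."""


class DegenerateInputError(BspmError):
    """Input is degenerate for the requested operation (e.g. zero power)."""


class EmptyInputError(BspmError):
    """An operation that needs at least one element received none."""


class AmbiguityError(BspmError):
    """Coincident interpolation nodes carry conflicting values."""


class UndefinedMetricError(BspmError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
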