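"""Exception hierarchy.

All package errors derive from :class:`DimergateError` so callers can catch
one base class; subclasses distinguish user/configuration mistakes from
malformed inputs and numerical failures.
"""


class DimergateError(Exception):
    """Base class for all errors raised by dimergate."""


class FormatError(DimergateError):
    """A structure or trajectory file could not be parsed."""


class RangeError(DimergateError, IndexError):
    """A requested model/step index is outside the available range."""


class SelectionError(DimergateError):
    """An atom selection is empty or otherwise unusable."""


class ConfigurationError(DimergateError):
    """Inconsistent chain roles, maps, layers or run configuration."""


class ConsistencyError(DimergateError):
    """Frames/models disagree with the selection they must cover."""


class ShapeError(DimergateError, ValueError):
    """Coordinate arrays have incompatible shapes."""


class ConditioningError(DimergateError):
    """Geometry is too degenerate for a well-defined superposition."""


class EmptyInputError(DimergateError):
    """An operation that needs at least one frame/pair received none."""


class ConnectivityError(DimergateError):
    """The elastic network of a toy homodimer is not connected."""


class InstabilityError(DimergateError):
    """A steered run diverged; reduce the step size or raise friction."""
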