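"""Exception hierarchy for aaamorph.

Every error raised by the library derives from :class:`AAAMorphError`, so
callers (and the CLI) can distinguish library failures from programming
errors with a single ``except`` clause.
"""


class AAAMorphError(Exception):
    """Base class for all aaamorph errors."""


class FormatError(AAAMorphError):
    """A mesh or volume file could not be parsed in the requested format."""


class SchemaError(AAAMorphError):
    """A centerline JSON file does not match the expected schema."""


class ValidationError(AAAMorphError):
    """A domain object violates one of its invariants or preconditions."""


class GeometryError(AAAMorphError):
    """Geometric input is unusable (grid mismatch, tangent flip, ...)."""


class NoContourError(AAAMorphError):
    """A contour was requested from an empty contour list."""


class EmptyResultError(AAAMorphError):
    """A mesh operation produced no geometry (e.g. cut removed everything)."""


class MeasurementFailureError(AAAMorphError):
    """A landmark could not be measured (centerline misses the mesh, ...)."""


class DegenerateCenterlineError(AAAMorphError):
    """A centerline chord is too short for a ratio or angle to be defined."""


class UndefinedDistanceError(AAAMorphError):
    """A surface distance was requested against an empty label mask."""


class InputError(AAAMorphError):
    """Invalid user-facing input (tables, specs, file arguments)."""
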