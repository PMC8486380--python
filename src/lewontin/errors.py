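"""Exception hierarchy shared across the package."""


class LewontinError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LewontinError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(LewontinError):
    """Too few observations for the requested fit or test."""


class DegenerateGeometryError(LewontinError):
    """Point set cannot support an alpha-shape (too few or collinear points).

    Callers should fall back to a fixed-radius buffer around the points.
    """


class EmptyRangeError(LewontinError):
    """Clipping a range against landmasses left nothing behind."""


class InvalidGeometryError(LewontinError):
    """A polygon is self-intersecting or otherwise invalid."""


class InvalidTreeError(LewontinError):
    """Tree fails a structural requirement (ultrametry, branch lengths, binary)."""


class SchemaError(LewontinError):
    """Tabular input is missing required columns or has malformed values."""
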