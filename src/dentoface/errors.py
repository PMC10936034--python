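"""Exception hierarchy.

All package-raised errors derive from :class:`DentofaceError` so callers
(and the CLI) can separate user-input problems from genuine bugs.
"""


class DentofaceError(Exception):
    """Base class for all errors raised by dentoface."""


class MeshParseError(DentofaceError):
    """A mesh file could not be parsed or violates mesh invariants."""


class LandmarkError(DentofaceError):
    """Unknown or missing anatomical landmark names."""


class ContourError(DentofaceError):
    """A polyline/contour violates its invariants or has an unsupported label."""


class DegenerateGeometryError(DentofaceError):
    """A geometric construction is degenerate (collinear plane points,
    zero-length angle arm, horizontal reference line, ...)."""


class CoverageError(DentofaceError):
    """A lip contour does not span the X position where a tooth measurement
    needs to intersect it."""


class MissingInputError(DentofaceError):
    """A required contour or landmark is absent from the case."""


class RegistrationError(DentofaceError):
    """Point-set registration cannot proceed (too few or degenerate pairs)."""


class PhantomConstructionError(DentofaceError):
    """A synthetic-case parameter combination is geometrically inconsistent."""


class StatisticsError(DentofaceError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
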