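"""Exception hierarchy.

All package errors derive from :class:`NucstackError` so callers can catch
one base class; subclasses distinguish I/O, annotation, geometry and
validation failures.
"""


class NucstackError(Exception):
    """Base class for all errors raised by nucstack."""


class EmptyStructureError(NucstackError):
    """A parsed file contained no atoms."""


class TopologyError(NucstackError):
    """Models of a trajectory file do not share one topology."""


class AnnotationError(NucstackError):
    """Chain-role annotation is inconsistent with the structure."""


class ValidationError(NucstackError):
    """An input value violates a documented contract."""


class PairingError(NucstackError):
    """DNA strands cannot be paired base-by-base."""


class GapError(NucstackError):
    """Required atoms or base pairs are missing."""


class GeometryError(NucstackError):
    """Degenerate geometry (collinear points, zero-length axes, ...)."""


class RangeError(NucstackError):
    """A coordinate or index is outside its admissible range."""


class StateError(NucstackError):
    """An operation was called on an object in the wrong state."""


class SelectionError(NucstackError):
    """An atom/residue selection matched nothing."""


class SpecError(NucstackError):
    """A synthetic-structure specification is geometrically impossible."""


class GridError(NucstackError):
    """Two profiles are defined on different fraction grids."""


class NormalizationError(NucstackError):
    """A profile cannot be normalized (e.g. all-zero intensities)."""


class InterpolationError(NucstackError):
    """Too few points for the requested interpolation scheme."""


class InsufficientDataError(NucstackError):
    """Not enough ordered nucleosomes (or frames) for the analysis."""
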