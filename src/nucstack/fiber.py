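"""Nucleosomal-array geometry: step series, start number, helix fit.

An array is analyzed as an ordered list of nucleosome reference frames
(order comes from the annotation, i.e. the repeat index along the DNA,
not from tracing linker connectivity).  From the frames we derive:

* step parameters between consecutive (n, n+1) and next-nearest
  (n, n+2) nucleosomes;
* the start number — 2 when the n+2 partner is the closer stacking
  partner (two intertwined stacks, zig-zag), 1 for consecutive
  (solenoid-like) stacking;
* fiber helical parameters in the base-pair analogy: the fiber axis,
  rise and twist per nucleosome, and the mean distance/angle between
  stacked (n, n+2) pairs.  The axis is found from second differences of
  the origins (which are exactly perpendicular to the axis for points
  on a circular helix), the in-plane circle center by algebraic
  least squares, and azimuths are unwrapped by nearest-branch
  continuation to avoid ±360° jumps.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .errors import GeometryError, InsufficientDataError, ValidationError
from .frames import NucleosomeFrame
from .stacking import StackStep, nucleosome_frame, step_parameters
from .structio import AnnotatedComplex

__all__ = [
    "FiberGeometry",
    "ArrayDefinition",
    "OrderedNucleosome",
    "order_nucleosomes",
    "fiber_steps",
    "classify_start_number",
    "StartClassification",
    "fiber_helix_fit",
    "linker_accounting",
]


@dataclass
class OrderedNucleosome:
    nucleosome_id: str
    frame: NucleosomeFrame | None   # None for flexible nucleosomes
    ordered: bool


@dataclass
class FiberGeometry:
    """Helical description of an array, by analogy with a base stack.

    ``stacked_pair_distance``/``stacked_pair_angle`` are the mean
    origin–origin distance and mean inter-z-axis angle over (n, n+2)
    pairs — this package's operational definition of the spacing and
    inclination of stacking partners.
    """

    axis_direction: np.ndarray      # unit vector
    axis_point: np.ndarray          # a point on the axis
    rise_per_nucleosome: float      # A
    twist_per_nucleosome: float     # degrees, signed (right-hand about axis)
    start_number: int               # 1 or 2
    stacked_pair_distance: float    # A, mean over (n, n+2)
    stacked_pair_angle: float       # degrees, mean over (n, n+2)
    n_ordered: int


@dataclass
class ArrayDefinition:
    """Repeat bookkeeping of a reconstituted array (e.g. 12x167 bp)."""

    n_repeats: int
    repeat_length: int    # bp per tandem repeat
    wrapped_length: int = 147
    terminal_flexible_count: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValidationError("need at least one repeat")
        if self.repeat_length < self.wrapped_length:
            raise ValidationError(
                f"repeat length {self.repeat_length} shorter than wrapped "
                f"length {self.wrapped_length}")


@dataclass
class StartClassification:
    start_number: int
    partner_offset: int            # 1 or 2
    median_distance_n1: float
    median_distance_n2: float
    status: str                    # "ok" | "ambiguous"


def order_nucleosomes(complex_: AnnotatedComplex
                      ) -> list[OrderedNucleosome]:
    """Frames of the array's nucleosomes in annotation order.

    Nucleosomes flagged flexible in the annotation get no frame and are
    excluded from all geometry fits.  Fewer than two ordered nucleosomes
    raises :class:`~nucstack.errors.InsufficientDataError`.
    """
    if len(complex_.nucleosomes) < 2:
        raise InsufficientDataError("array must contain at least 2 nucleosomes")
    out: list[OrderedNucleosome] = []
    for nuc in complex_.nucleosomes:
        if nuc.flexible:
            out.append(OrderedNucleosome(nuc.nucleosome_id, None, False))
        else:
            frame = nucleosome_frame(complex_, nuc.nucleosome_id)
            out.append(OrderedNucleosome(nuc.nucleosome_id, frame, True))
    n_ordered = sum(o.ordered for o in out)
    if n_ordered < 2:
        raise InsufficientDataError(
            f"only {n_ordered} ordered nucleosome(s); need >= 2")
    return out


def _ordered_frames(ordered: list[OrderedNucleosome]) -> list[NucleosomeFrame]:
    return [o.frame for o in ordered if o.ordered and o.frame is not None]


def fiber_steps(ordered: list[OrderedNucleosome]
                ) -> tuple[list[StackStep], list[StackStep]]:
    """Step-parameter series for offsets 1 and 2 over ordered frames.

    For N ordered nucleosomes the series have lengths N−1 and N−2.
    """
    frames = _ordered_frames(ordered)
    if len(frames) < 3:
        raise InsufficientDataError(
            f"need >= 3 ordered nucleosomes for step series, got {len(frames)}")
    steps1 = [step_parameters(frames[i], frames[i + 1])
              for i in range(len(frames) - 1)]
    steps2 = [step_parameters(frames[i], frames[i + 2])
              for i in range(len(frames) - 2)]
    return steps1, steps2


def classify_start_number(steps1: list[StackStep], steps2: list[StackStep],
                          tie_tolerance: float = 1e-6) -> StartClassification:
    """Start number from median center distances at offsets 1 and 2.

    Two-start (zig-zag) when the n+2 partner is closer than the n+1
    neighbor; a tie within ``tie_tolerance`` (relative) is reported as
    ambiguous rather than silently resolved.
    """
    if not steps1 or not steps2:
        raise InsufficientDataError("empty step series")
    d1 = median(s.center_distance for s in steps1)
    d2 = median(s.center_distance for s in steps2)
    scale = max(d1, d2, 1e-12)
    if abs(d1 - d2) <= tie_tolerance * scale:
        return StartClassification(2 if d2 < d1 else 1, 2 if d2 < d1 else 1,
                                   d1, d2, "ambiguous")
    if d2 < d1:
        return StartClassification(2, 2, d1, d2, "ok")
    return StartClassification(1, 1, d1, d2, "ok")


def _fiber_axis(origins: np.ndarray) -> np.ndarray:
    """Axis direction from second differences of consecutive origins.

    For points on a circular helix the second differences lie exactly in
    the plane perpendicular to the axis, so the axis is the smallest
    principal direction of their scatter — exact for noiseless input.
    """
    second = np.diff(origins, n=2, axis=0)
    if len(second) < 2:
        raise GeometryError("need >= 4 origins for axis estimation")
    norms = np.linalg.norm(second, axis=1)
    if np.max(norms) < 1e-9:
        raise GeometryError("origins are collinear; no defined fiber axis")
    _, s, vt = np.linalg.svd(second, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        # all second differences parallel: degenerate planar arrangement
        raise GeometryError("degenerate (coplanar) origin arrangement")
    return vt[2]


def _circle_center(points2d: np.ndarray) -> np.ndarray:
    """Algebraic (Kasa) circle fit; exact for points on a circle."""
    x, y = points2d[:, 0], points2d[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def fiber_helix_fit(ordered: list[OrderedNucleosome]) -> FiberGeometry:
    """Fit the helical fiber parameters from ordered nucleosome frames.

    Rise and twist per nucleosome are the mean consecutive axial and
    azimuthal increments about the fitted axis; the axis sign is chosen
    so the rise is positive, making the twist sign a right-hand-rule
    statement about the advancing fiber.
    """
    frames = _ordered_frames(ordered)
    if len(frames) < 4:
        raise InsufficientDataError(
            f"need >= 4 ordered nucleosomes for a helix fit, got {len(frames)}")
    origins = np.array([f.origin for f in frames])
    axis = _fiber_axis(origins)
    heights = origins @ axis
    rises = np.diff(heights)
    if rises.mean() < 0:
        axis = -axis
        heights = -heights
        rises = -rises
    rise = float(rises.mean())

    # in-plane coordinates about the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    uv = np.column_stack([origins @ e1, origins @ e2])
    center = _circle_center(uv)
    rel = uv - center
    radii = np.linalg.norm(rel, axis=1)
    if np.min(radii) < 1e-9:
        raise GeometryError("origin on the fiber axis; azimuth undefined")
    azimuth = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    increments = (np.diff(azimuth) + 180.0) % 360.0 - 180.0  # nearest branch
    twist = float(increments.mean())

    d2 = [float(np.linalg.norm(origins[i + 2] - origins[i]))
          for i in range(len(origins) - 2)]
    a2 = [float(np.degrees(np.arccos(np.clip(frames[i].z @ frames[i + 2].z,
                                             -1.0, 1.0))))
          for i in range(len(frames) - 2)]
    d1 = [float(np.linalg.norm(origins[i + 1] - origins[i]))
          for i in range(len(origins) - 1)]
    start = 2 if np.mean(d2) < np.mean(d1) else 1

    axis_point = np.zeros(3) + center[0] * e1 + center[1] * e2 \
        + heights.mean() * axis
    return FiberGeometry(
        axis_direction=axis,
        axis_point=axis_point,
        rise_per_nucleosome=rise,
        twist_per_nucleosome=twist,
        start_number=start,
        stacked_pair_distance=float(np.mean(d2)),
        stacked_pair_angle=float(np.mean(a2)),
        n_ordered=len(frames),
    )


def linker_accounting(array: ArrayDefinition) -> int:
    """Linker length in bp: repeat length minus wrapped length."""
    return array.repeat_length - array.wrapped_length
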