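"""Ensemble alignment and inter-nucleosome step parameters.

A stacked-nucleosome geometry is summarized by rigid-body step
parameters between the two nucleosome reference frames, by analogy with
DNA base-step parameters:

* the *mid-frame* is the rotational midpoint (quaternion interpolation
  at t = 1/2) of the two axis sets, with origin at the origin midpoint;
* **rise** is the origin displacement along the mid-frame z axis and
  **shift_x / shift_y** are the in-plane components, so that
  ``center_distance² = rise² + shift_x² + shift_y²`` exactly;
* **tilt** is the total angle between the two superhelical (z) axes;
* **twist** is the signed angle (right-hand rule about mid-frame z)
  between the projections of the two dyad (y) axes.

Trajectory ensembles are aligned by least-squares (Kabsch) superposition
of the C1′ atoms of one reference nucleosome in every frame onto those
of a reference frame; the dyad/anti-dyad marker points of the mobile
nucleosome then trace the sampling cloud of relative nucleosome motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import GapError, GeometryError, PairingError, StateError, ValidationError
from .frames import (
    DEFAULT_ANTI_DYAD_INDICES,
    NucleosomeFrame,
    compute_frame,
    dyad_points,
    pair_base_steps,
)
from .structio import AnnotatedComplex, TrajectoryEnsemble

__all__ = [
    "RigidTransform",
    "StackStep",
    "PointCloudSummary",
    "superpose",
    "align_ensemble",
    "sampling_cloud",
    "step_parameters",
    "step_to_transform",
    "ensemble_step_stats",
    "nucleosome_frame",
]

STEP_PARAMETER_NAMES = ("rise", "shift_x", "shift_y", "tilt", "twist",
                        "center_distance")


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValidationError("rotation not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("improper rotation (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class StackStep:
    """Rigid-body step between two nucleosome frames.

    Distances in Angstrom, angles in degrees; ``center_distance`` is
    derived from the displacement components.
    """

    rise: float
    shift_x: float
    shift_y: float
    tilt: float
    twist: float
    center_distance: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt <= 180.0:
            raise ValidationError(f"tilt {self.tilt} outside [0, 180]")
        if not -180.0 < self.twist <= 180.0:
            raise ValidationError(f"twist {self.twist} outside (-180, 180]")
        self.center_distance = float(
            np.sqrt(self.rise ** 2 + self.shift_x ** 2 + self.shift_y ** 2))

    def as_array(self) -> np.ndarray:
        return np.array([self.rise, self.shift_x, self.shift_y,
                         self.tilt, self.twist, self.center_distance])


@dataclass
class PointCloudSummary:
    """Dyad / anti-dyad sampling clouds of a mobile nucleosome."""

    nucleosome_id: str
    dyad_points: np.ndarray        # (n_frames, 3) aligned coordinates
    anti_dyad_points: np.ndarray   # (n_frames, 3)
    dyad_rms: float                # RMS distance of points to their centroid
    anti_dyad_rms: float
    dyad_axes: np.ndarray          # (3, 3) principal axes (rows)
    dyad_extents: np.ndarray       # (3,) RMS extent along each axis
    anti_dyad_axes: np.ndarray
    anti_dyad_extents: np.ndarray

    @property
    def frame_count(self) -> int:
        return self.dyad_points.shape[0]


def superpose(reference: np.ndarray, mobile: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing the RMSD of
    ``R @ mobile + t`` to ``reference`` plus that minimal RMSD.
    Reflections are excluded: for a mirror-image pair the returned
    rotation still has det = +1 and the RMSD stays positive.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise PairingError(f"point sets differ in shape: {ref.shape} vs {mob.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise PairingError("need >= 3 corresponding 3D points")
    cref = ref.mean(axis=0)
    cmob = mob.mean(axis=0)
    H = (mob - cmob).T @ (ref - cref)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise GeometryError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cref - R @ cmob
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _reference_c1_indices(complex_: AnnotatedComplex, nucleosome_id: str
                          ) -> np.ndarray:
    nuc = complex_.nucleosome(nucleosome_id)
    struct = complex_.structure
    idx = struct.atom_indices(chain=list(nuc.dna_chains), atom_name="C1'")
    if len(idx) == 0:
        raise GapError(f"nucleosome {nucleosome_id!r} has no C1' atoms")
    return idx


def align_ensemble(ensemble: TrajectoryEnsemble, reference_nucleosome_id: str,
                   reference_frame_index: int = 0) -> TrajectoryEnsemble:
    """Rigidly align every frame on one nucleosome's C1′ atoms.

    Each frame is transformed so its reference-nucleosome C1′ set
    superposes with minimum RMSD onto the same atoms in
    ``reference_frame_index``.  Atom identity and frame order are
    preserved; the result is flagged as aligned on that nucleosome.
    """
    idx = _reference_c1_indices(ensemble.topology, reference_nucleosome_id)
    nref = ensemble.frames[reference_frame_index][idx]
    if not np.all(np.isfinite(ensemble.frames[:, idx])):
        bad = np.nonzero(~np.isfinite(ensemble.frames[:, idx]).all(axis=(1, 2)))[0]
        raise GapError(f"non-finite C1' coordinates in frame {bad[0]}")
    aligned = np.empty_like(ensemble.frames)
    for i in range(ensemble.frame_count):
        tf, _ = superpose(nref, ensemble.frames[i][idx])
        aligned[i] = tf.apply(ensemble.frames[i])
    return TrajectoryEnsemble(ensemble.topology, aligned,
                              aligned_on=reference_nucleosome_id)


def _cloud_stats(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    centered = points - points.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))
    cov = centered.T @ centered / max(len(points), 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return rms, evecs[:, order].T, np.sqrt(np.maximum(evals[order], 0.0))


def sampling_cloud(aligned: TrajectoryEnsemble, mobile_nucleosome_id: str,
                   anti_indices: Sequence[int] = DEFAULT_ANTI_DYAD_INDICES,
                   ) -> PointCloudSummary:
    """Per-frame dyad/anti-dyad points of the mobile nucleosome.

    Requires an ensemble aligned on some reference nucleosome (a
    :class:`~nucstack.errors.StateError` otherwise).  RMS dispersion is
    the root-mean-square distance of the marker points to their
    centroid; principal axes/extents describe cloud anisotropy.
    """
    if aligned.aligned_on is None:
        raise StateError("ensemble is not aligned; run align_ensemble first")
    topo = aligned.topology
    dyads = np.empty((aligned.frame_count, 3))
    antis = np.empty((aligned.frame_count, 3))
    for i in range(aligned.frame_count):
        series = pair_base_steps(aligned.frame_complex(i), mobile_nucleosome_id)
        dyads[i], antis[i] = dyad_points(series, anti_indices)
    drms, daxes, dext = _cloud_stats(dyads)
    arms, aaxes, aext = _cloud_stats(antis)
    return PointCloudSummary(mobile_nucleosome_id, dyads, antis,
                             drms, arms, daxes, dext, aaxes, aext)


# ---------------------------------------------------------------------------
# step parameters
# ---------------------------------------------------------------------------

def _mid_rotation(R1: np.ndarray, R2: np.ndarray) -> np.ndarray:
    rel = Rotation.from_matrix(R2 @ R1.T)
    return (rel ** 0.5).as_matrix() @ R1


def _decompose(R1: np.ndarray, O1: np.ndarray, R2: np.ndarray, O2: np.ndarray
               ) -> tuple[float, float, float, float, float, float]:
    """(rise, shift_x, shift_y, tilt, twist, hinge phase) of frame 2
    relative to frame 1 under the mid-frame convention."""
    Rm = _mid_rotation(R1, R2)
    xm, ym, zm = Rm[:, 0], Rm[:, 1], Rm[:, 2]
    d = O2 - O1
    rise = float(d @ zm)
    sx, sy = float(d @ xm), float(d @ ym)
    z1, z2 = R1[:, 2], R2[:, 2]
    # atan2 form is accurate for near-parallel and near-antiparallel axes
    tilt = float(np.degrees(np.arctan2(np.linalg.norm(np.cross(z1, z2)),
                                       z1 @ z2)))
    y1p = R1[:, 1] - (R1[:, 1] @ zm) * zm
    y2p = R2[:, 1] - (R2[:, 1] @ zm) * zm
    n1, n2 = np.linalg.norm(y1p), np.linalg.norm(y2p)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("dyad axis parallel to mid-frame z; twist undefined")
    y1p, y2p = y1p / n1, y2p / n2
    twist = float(np.degrees(np.arctan2(np.cross(y1p, y2p) @ zm, y1p @ y2p)))
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) > 1e-12:
        phase = float(np.degrees(np.arctan2(hinge @ ym, hinge @ xm)))
    else:
        phase = 0.0
    return rise, sx, sy, tilt, twist, phase


def step_parameters(frame1: NucleosomeFrame, frame2: NucleosomeFrame
                    ) -> StackStep:
    """Rigid-body step of ``frame2`` relative to ``frame1``.

    Invariant under any global proper rigid motion applied to both
    frames; swapping the frames negates rise and twist while preserving
    their magnitudes and the tilt.
    """
    frame1.validate(tol=1e-6)
    frame2.validate(tol=1e-6)
    rise, sx, sy, tilt, twist, _ = _decompose(
        frame1.rotation, frame1.origin, frame2.rotation, frame2.origin)
    twist = twist if twist > -180.0 else 180.0
    return StackStep(rise, sx, sy, min(max(tilt, 0.0), 180.0), twist)


def step_to_transform(frame1: NucleosomeFrame, step: StackStep,
                      hinge_phase: float = 0.0) -> RigidTransform:
    """The rigid motion carrying ``frame1`` to a frame at exactly ``step``.

    Exact inverse of :func:`step_parameters`: applying the returned
    transform to a nucleosome sitting in ``frame1`` produces a second
    frame whose step parameters relative to ``frame1`` equal ``step`` to
    numerical precision.  ``hinge_phase`` (degrees) sets the azimuth of
    the tilt hinge axis in the mid-frame; it does not change any of the
    five reported parameters.
    """
    tilt, twist = float(step.tilt), float(step.twist)
    if tilt < 1e-10:
        Rrel = Rotation.from_euler("z", twist, degrees=True).as_matrix()
    else:
        target = np.array([tilt, twist, hinge_phase])

        def residuals(v: np.ndarray) -> np.ndarray:
            R2 = Rotation.from_rotvec(v).as_matrix()
            _, _, _, t, w, p = _decompose(np.eye(3), np.zeros(3), R2, np.zeros(3))
            return np.array([
                t - target[0],
                np.sin(np.radians(w - target[1])) * 180.0 / np.pi,
                np.sin(np.radians(p - target[2])) * tilt / 57.29577951308232,
            ])

        hinge = Rotation.from_euler("z", hinge_phase, degrees=True).apply([1, 0, 0])
        x0 = Rotation.from_matrix(
            Rotation.from_rotvec(np.radians(tilt) * hinge).as_matrix()
            @ Rotation.from_euler("z", twist, degrees=True).as_matrix()
        ).as_rotvec()
        sol = least_squares(residuals, x0, xtol=3e-16, ftol=3e-16, gtol=3e-16)
        if np.max(np.abs(sol.fun)) > 1e-8:
            raise GeometryError(
                f"step inversion did not converge (residual {np.max(np.abs(sol.fun)):.2e})")
        Rrel = Rotation.from_rotvec(sol.x).as_matrix()

    Rm_local = (Rotation.from_matrix(Rrel) ** 0.5).as_matrix()
    d_local = (step.rise * Rm_local[:, 2] + step.shift_x * Rm_local[:, 0]
               + step.shift_y * Rm_local[:, 1])
    B = frame1.rotation
    R_world = B @ Rrel @ B.T
    O2 = frame1.origin + B @ d_local
    t = O2 - R_world @ frame1.origin
    return RigidTransform(R_world, t)


def nucleosome_frame(complex_: AnnotatedComplex, nucleosome_id: str
                     ) -> NucleosomeFrame:
    """Convenience: base-pair series then reference frame."""
    return compute_frame(pair_base_steps(complex_, nucleosome_id))


def ensemble_step_stats(aligned: TrajectoryEnsemble, id1: str, id2: str
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame step parameters between two nucleosomes plus summary.

    Returns ``(series, summary)``: one row per frame with the six step
    quantities, and mean / s.d. (ddof=1) / min / max per parameter,
    recomputable from the series.
    """
    rows = []
    for i in range(aligned.frame_count):
        fc = aligned.frame_complex(i)
        try:
            f1 = nucleosome_frame(fc, id1)
            f2 = nucleosome_frame(fc, id2)
        except (GeometryError, GapError, PairingError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        step = step_parameters(f1, f2)
        rows.append({"frame": i, **dict(zip(STEP_PARAMETER_NAMES,
                                            step.as_array()))})
    series = pd.DataFrame(rows)
    params = series[list(STEP_PARAMETER_NAMES)]
    summary = pd.DataFrame({
        "mean": params.mean(),
        "sd": params.std(ddof=1) if len(series) > 1 else params.std(ddof=0),
        "min": params.min(),
        "max": params.max(),
    })
    return series, summary
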