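"""Per-nucleosome geometry: base-pair series, reference frames, SHL.

The geometric primitive for everything here is the C1′ atom of each
nucleotide.  Two antiparallel strands are paired base-by-base (strand 1
residue *j*, 5′→3′, with strand 2 residue *N−1−j*), the midpoint of the
two C1′ atoms defines the base-pair center, and the ordered centers give:

* a nucleosome reference frame — origin at the centroid of the wrapped
  bp centers, ``z`` the superhelical axis (best-fit plane normal, signed
  so the left-handed wrap runs clockwise seen from +z), ``y`` pointing
  from the origin toward the dyad, ``x = y × z``;
* a continuous superhelical location (SHL) for every base pair,
  ``SHL = bp_index / 10.4`` with the dyad at 0;
* the dyad and anti-dyad marker points used for sampling clouds
  (centroids of the C1′ atoms at bp −1..+1 and at bp ±36/±37, the disc
  position diametrically opposite the dyad, ≈ SHL ±3.5).

Base pairs flagged as not stably bound (flexible terminal DNA, as in
CENP-A nucleosomes) stay in the series but are excluded from frame
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GapError, GeometryError, PairingError, RangeError, ValidationError
from .structio import AnnotatedComplex

BP_PER_SHL = 10.4          # base pairs per superhelical turn of the duplex
MAX_WRAPPED_SHL = 7.3      # |SHL| bound for wrapped DNA
DEFAULT_ANTI_DYAD_INDICES = (36, 37)

__all__ = [
    "BasePairSeries",
    "NucleosomeFrame",
    "BP_PER_SHL",
    "pair_base_steps",
    "compute_frame",
    "shl_of",
    "dyad_points",
]


@dataclass
class BasePairSeries:
    """Paired C1′ geometry of one nucleosome's DNA wrap.

    ``indices`` are contiguous integers with 0 at the dyad; negative
    values run toward the strand-1 5′ terminus.
    """

    nucleosome_id: str
    indices: np.ndarray            # (n,) int, contiguous
    c1_strand1: np.ndarray         # (n, 3) C1′ of strand 1
    c1_strand2: np.ndarray         # (n, 3) C1′ of strand 2
    stably_bound: np.ndarray       # (n,) bool
    strand1_chain: str
    strand2_chain: str
    strand1_resids: np.ndarray     # (n,) int residue index on strand 1
    strand2_resids: np.ndarray     # (n,) int residue index on strand 2
    bp_centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) != 1):
            raise ValidationError("bp indices must be contiguous ascending")
        self.c1_strand1 = np.asarray(self.c1_strand1, dtype=float)
        self.c1_strand2 = np.asarray(self.c1_strand2, dtype=float)
        self.stably_bound = np.asarray(self.stably_bound, dtype=bool)
        self.bp_centers = 0.5 * (self.c1_strand1 + self.c1_strand2)

    @property
    def n_bp(self) -> int:
        return len(self.indices)

    def position_of(self, index: int) -> int:
        """Array position of bp ``index``; GapError if absent."""
        pos = index - int(self.indices[0])
        if pos < 0 or pos >= self.n_bp:
            raise GapError(
                f"base pair {index} absent from series "
                f"[{self.indices[0]}..{self.indices[-1]}]")
        return pos

    def bp_index_of_residue(self, chain: str, resid: int) -> int:
        """Map a (chain, residue) nucleotide to its bp index."""
        if chain == self.strand1_chain:
            hits = np.nonzero(self.strand1_resids == resid)[0]
        elif chain == self.strand2_chain:
            hits = np.nonzero(self.strand2_resids == resid)[0]
        else:
            raise GapError(f"chain {chain!r} is not a strand of "
                           f"nucleosome {self.nucleosome_id!r}")
        if len(hits) == 0:
            raise GapError(f"residue {chain}/{resid} not in base-pair series")
        return int(self.indices[hits[0]])

    def shl(self) -> np.ndarray:
        """Continuous SHL value for every base pair."""
        return self.indices / BP_PER_SHL


@dataclass
class NucleosomeFrame:
    """Origin plus orthonormal right-handed axes of one nucleosome."""

    origin: np.ndarray   # (3,)
    x: np.ndarray        # (3,) unit
    y: np.ndarray        # (3,) unit, toward the dyad
    z: np.ndarray        # (3,) unit, superhelical axis

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.validate()

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns (x, y, z)."""
        return np.column_stack([self.x, self.y, self.z])

    def validate(self, tol: float = 1e-6) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise ValidationError("frame axes not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("frame axes are left-handed")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "NucleosomeFrame":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return NucleosomeFrame(R @ self.origin + t, R @ self.x, R @ self.y, R @ self.z)


def pair_base_steps(complex_: AnnotatedComplex, nucleosome_id: str
                    ) -> BasePairSeries:
    """Pair the two DNA strands of a nucleosome into a base-pair series.

    Strand-1 residue *j* (counting 5′→3′ in residue order) is paired with
    strand-2 residue *N−1−j*; the dyad index 0 sits at the central pair
    (odd N) or at the 5′ member of the central pair on strand 1 (even N).
    Terminal base pairs within the annotation's ``flexible_bp_per_end``
    are flagged ``stably_bound = False``.
    """
    nuc = complex_.nucleosome(nucleosome_id)
    struct = complex_.structure
    strands: list[tuple[np.ndarray, np.ndarray]] = []
    for chain in nuc.dna_chains:
        chain_idx = struct.atom_indices(chain=chain)
        if len(chain_idx) == 0:
            raise GapError(f"DNA chain {chain!r} has no atoms")
        resids = struct.residue_indices[chain_idx]
        order = np.argsort(resids, kind="stable")
        chain_idx = chain_idx[order]
        resids = resids[order]
        uniq = np.unique(resids)
        c1_positions = []
        missing = []
        for r in uniq:
            sel = chain_idx[(resids == r) & (struct.atom_names[chain_idx] == "C1'")]
            if len(sel) == 0:
                missing.append(int(r))
            else:
                c1_positions.append(sel[0])
        if missing:
            raise GapError(
                f"chain {chain!r} missing C1' atoms for residues {missing}")
        strands.append((uniq, np.array(c1_positions, dtype=int)))

    (res1, idx1), (res2, idx2) = strands
    n1, n2 = len(idx1), len(idx2)
    if n1 != n2:
        raise PairingError(
            f"nucleosome {nucleosome_id!r}: strand lengths differ ({n1} vs {n2})")
    n = n1
    coords = struct.coords[0]
    # strand 2 in antiparallel register: residue N-1-j pairs residue j
    idx2_rev = idx2[::-1]
    res2_rev = res2[::-1]
    dyad_pos = (n - 1) // 2 if n % 2 == 1 else n // 2 - 1
    indices = np.arange(n) - dyad_pos
    f = nuc.flexible_bp_per_end
    stably = np.ones(n, dtype=bool)
    if f > 0:
        stably[:f] = False
        stably[n - f:] = False
    return BasePairSeries(
        nucleosome_id=nucleosome_id,
        indices=indices,
        c1_strand1=coords[idx1],
        c1_strand2=coords[idx2_rev],
        stably_bound=stably,
        strand1_chain=nuc.dna_chains[0],
        strand2_chain=nuc.dna_chains[1],
        strand1_resids=res1.astype(int),
        strand2_resids=res2_rev.astype(int),
    )


def compute_frame(series: BasePairSeries) -> NucleosomeFrame:
    """Nucleosome reference frame from a base-pair series.

    Uses only stably bound base pairs; requires at least 20 spanning the
    dyad.  The superhelical axis is the smallest principal direction of
    the bp centers, signed so the bp path from low to high index advances
    clockwise viewed from +z (left-handed wrap); ``y`` is the in-plane
    unit vector from origin to the dyad bp center.
    """
    mask = series.stably_bound
    pts = series.bp_centers[mask]
    idxs = series.indices[mask]
    if len(pts) < 20 or idxs.min() >= 0 or idxs.max() <= 0:
        raise GeometryError(
            f"need >= 20 stably bound base pairs spanning the dyad, "
            f"got {len(pts)} in [{idxs.min() if len(idxs) else '-'}.."
            f"{idxs.max() if len(idxs) else '-'}]")
    origin = pts.mean(axis=0)
    centered = pts - origin
    # best-fit plane: smallest right singular vector
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("bp centers are collinear; no defined plane")
    z = vt[2]
    # orient z: path must run clockwise seen from +z (negative circulation)
    circulation = np.sum(np.cross(centered[:-1], centered[1:]) @ z)
    if circulation > 0:
        z = -z
    dyad_center = series.bp_centers[series.position_of(0)]
    y = dyad_center - origin
    y = y - (y @ z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise GeometryError("dyad bp center projects onto the frame origin")
    y = y / ny
    x = np.cross(y, z)
    return NucleosomeFrame(origin, x, y, z)


def shl_of(bp_index: float | int) -> float:
    """Continuous superhelical location of a base-pair index (dyad = 0)."""
    if abs(bp_index) > 73:
        raise RangeError(f"bp index {bp_index} outside wrapped range [-73, 73]")
    return float(bp_index) / BP_PER_SHL


def dyad_points(series: BasePairSeries,
                anti_indices: Sequence[int] = DEFAULT_ANTI_DYAD_INDICES,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Dyad and anti-dyad marker points of a nucleosome.

    The dyad point is the geometric center of the C1′ atoms of base pairs
    −1, 0, +1.  The anti-dyad point is the center of the C1′ atoms at
    ``±i`` for each ``i`` in ``anti_indices`` (default ±36, ±37 — the
    disc position diametrically opposite the dyad).  The index set is a
    parameter so that other readings (e.g. the DNA termini, ±72/±73) can
    be reproduced.
    """

    def centroid(indices: Sequence[int]) -> np.ndarray:
        pos = [series.position_of(i) for i in indices]
        atoms = np.vstack([series.c1_strand1[pos], series.c1_strand2[pos]])
        return atoms.mean(axis=0)

    dyad = centroid([-1, 0, 1])
    anti = centroid([i for j in anti_indices for i in (j, -j)])
    return dyad, anti
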