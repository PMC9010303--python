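"""Synthetic pseudo-atomic structures with known ground truth.

Every analysis in this package is exercised against structures built
here: an idealized nucleosome (C1′ atoms of both strands traced along a
left-handed superhelix, histone placeholder pseudo-atoms inside the
gyres), a CENP-A-like variant with flexible terminal DNA, bridged
two-nucleosome stacks whose inter-nucleosome step parameters are set
exactly, 12-mer two-start fibers with prescribed per-nucleosome rise and
twist, and seeded Gaussian-jittered ensembles emulating the breadth of
relative sampling seen in stacked-nucleosome trajectories.

Histones and bridging factors are placeholder pseudo-atom chains, not
full-atom models: the analyses downstream only consume chain roles and
positions.  The factor placeholder carries residues numbered 102–117
with Lys/Arg names at the positions of the basic face of the CENP-N α6
helix, so interface reports on synthetic data read like reports on the
deposited structures.

Default superhelix radius (41.9 Å) and pitch (25.9 Å) are canonical
literature values for the nucleosome core particle; both are
overridable.  All stochastic operations require an explicit seed and are
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SpecError
from .stacking import (
    RigidTransform,
    StackStep,
    _decompose,
    nucleosome_frame,
    step_parameters,
    step_to_transform,
)
from .structio import (
    AnnotatedComplex,
    FactorAnnotation,
    NucleosomeAnnotation,
    StructureModel,
    TrajectoryEnsemble,
    role_map_of,
    save_role_map,
    write_structure,
)

__all__ = [
    "NucleosomeSpec",
    "StackSpec",
    "FiberSpec",
    "DispersionSpec",
    "build_nucleosome",
    "build_stack",
    "build_fiber",
    "sample_ensemble",
    "write_fixture",
    "nucleosome_preset",
    "dispersion_preset",
    "fiber_preset",
]

# basic face of the bridging factor's DNA-binding helix
ALPHA6_BASIC_RESIDUES = {102: "LYS", 105: "LYS", 109: "LYS", 110: "LYS",
                         114: "ARG", 117: "LYS"}
HISTONE_ORDER = ("H3", "H4", "H2A", "H2B")


@dataclass
class NucleosomeSpec:
    """Geometry of one idealized nucleosome."""

    n_bp: int = 147
    radius: float = 41.9            # superhelix radius, A
    pitch: float = 25.9             # superhelix pitch, A per turn
    c1_separation: float = 10.5     # C1'-C1' distance across a base pair, A
    wrap_turns: float = 1.65        # superhelical turns covered by the wrap
    flexible_bp_per_end: int = 0
    histone_atoms_per_chain: int = 10
    variant: str = "H3"             # "H3" or "CENP-A"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.pitch <= 0 or self.c1_separation <= 0:
            raise SpecError("radius, pitch and C1' separation must be positive")
        if self.n_bp < 3:
            raise SpecError("need at least 3 base pairs")
        if 2 * self.flexible_bp_per_end >= self.n_bp:
            raise SpecError("flexible ends cover the whole wrap")


def nucleosome_preset(name: str) -> NucleosomeSpec:
    """Named nucleosome variants.

    ``H3``: canonical, all 147 bp stably bound.  ``CENP-A``: 13 flexible
    bp per end, leaving 121 stably bound.
    """
    if name == "H3":
        return NucleosomeSpec()
    if name == "CENP-A":
        return NucleosomeSpec(flexible_bp_per_end=13, variant="CENP-A")
    raise SpecError(f"unknown nucleosome preset {name!r}")


@dataclass
class StackSpec:
    """Two bridged nucleosomes with an exact ground-truth step."""

    step: StackStep = field(default_factory=lambda: StackStep(60.0, 0.0, 0.0, 0.0, 20.0))
    n_factors: int = 1
    specific_anchor_bp: int = -25   # nuc-1 DNA bp near the factor body
    neighbor_anchor_bp: int = 47    # nuc-2 DNA bp under the basic helix face

    def __post_init__(self) -> None:
        if self.n_factors not in (0, 1, 2):
            raise SpecError("n_factors must be 0, 1 or 2")


@dataclass
class FiberSpec:
    """Helical nucleosomal array."""

    n_nucleosomes: int = 12
    rise_per_nucleosome: float = 30.0    # axial increment, A
    twist_per_nucleosome: float = 160.0  # azimuthal increment, degrees
    fiber_radius: float = 50.0           # nucleosome origins to fiber axis, A
    disc_tilt: float = 0.0               # nucleosome z tilt off the axis, degrees
    terminal_flexible_count: int = 0     # per end
    factors_per_step: int = 0            # bridging factors per (n, n+2) pair
    neighbor_anchor_bp: int = 65         # SHL ~6.25 on the n+2 nucleosome

    def __post_init__(self) -> None:
        if self.n_nucleosomes < 2:
            raise SpecError("need at least 2 nucleosomes")
        if self.factors_per_step not in (0, 1, 2):
            raise SpecError("factors_per_step must be 0, 1 or 2")
        if 2 * self.terminal_flexible_count >= self.n_nucleosomes:
            raise SpecError("flexible termini cover the whole array")


def fiber_preset(name: str) -> FiberSpec:
    """Named array geometries.

    ``cenpn_like``: two-start fiber with wide, strongly twisted (n, n+2)
    stacking and two bridging factors per stacked pair anchored at
    SHL 6–7 of the n+2 nucleosome.  ``h1_like``: two-start fiber with
    tighter stacking and shallower twist, no factors.  ``ladder``:
    parallel zig-zag with no net twist between stacked partners.
    """
    if name == "cenpn_like":
        return FiberSpec(rise_per_nucleosome=32.0, twist_per_nucleosome=162.0,
                         fiber_radius=55.0, disc_tilt=20.0,
                         terminal_flexible_count=2, factors_per_step=2,
                         neighbor_anchor_bp=65)
    if name == "h1_like":
        return FiberSpec(rise_per_nucleosome=27.0, twist_per_nucleosome=171.0,
                         fiber_radius=45.0, disc_tilt=8.0,
                         terminal_flexible_count=2, factors_per_step=0)
    if name == "ladder":
        return FiberSpec(rise_per_nucleosome=30.0, twist_per_nucleosome=180.0,
                         fiber_radius=40.0, disc_tilt=0.0, factors_per_step=0)
    raise SpecError(f"unknown fiber preset {name!r}")


@dataclass
class DispersionSpec:
    """Gaussian dispersion of the mobile nucleosome in an ensemble."""

    n_frames: int
    seed: int
    sigma_rise: float = 0.0        # A
    sigma_shift: float = 0.0       # A, applied to both in-plane components
    sigma_tilt: float = 0.0        # degrees
    sigma_twist: float = 0.0       # degrees
    coordinate_jitter: float = 0.0  # A, iid per coordinate of mobile atoms

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        for name in ("sigma_rise", "sigma_shift", "sigma_tilt", "sigma_twist",
                     "coordinate_jitter"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")


def dispersion_preset(name: str, n_frames: int, seed: int) -> DispersionSpec:
    """``bridged`` (factor-stabilized, narrow sampling) vs ``unbridged``
    (free stacking, wide sampling) dispersion presets."""
    if name == "bridged":
        return DispersionSpec(n_frames, seed, sigma_rise=0.8, sigma_shift=0.8,
                              sigma_tilt=2.0, sigma_twist=3.0)
    if name == "unbridged":
        return DispersionSpec(n_frames, seed, sigma_rise=6.0, sigma_shift=6.0,
                              sigma_tilt=12.0, sigma_twist=20.0)
    raise SpecError(f"unknown dispersion preset {name!r}")


# ---------------------------------------------------------------------------
# atom-list assembly
# ---------------------------------------------------------------------------

class _AtomList:
    def __init__(self) -> None:
        self.chain: list[str] = []
        self.resid: list[int] = []
        self.resname: list[str] = []
        self.atom: list[str] = []
        self.element: list[str] = []
        self.xyz: list[np.ndarray] = []

    def add(self, chain: str, resid: int, resname: str, atom: str,
            element: str, pos: np.ndarray) -> None:
        self.chain.append(chain)
        self.resid.append(resid)
        self.resname.append(resname)
        self.atom.append(atom)
        self.element.append(element)
        self.xyz.append(np.asarray(pos, dtype=float))

    def extend(self, other: "_AtomList") -> None:
        self.chain += other.chain
        self.resid += other.resid
        self.resname += other.resname
        self.atom += other.atom
        self.element += other.element
        self.xyz += other.xyz

    def to_model(self) -> StructureModel:
        return StructureModel(
            np.array(self.chain, dtype=object),
            np.array(self.resid, dtype=int),
            np.array(self.resname, dtype=object),
            np.array(self.atom, dtype=object),
            np.array(self.element, dtype=object),
            np.array(self.xyz, dtype=float)[None],
        )


def _superhelix_path(spec: NucleosomeSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """bp centers, tangents and pair-separation unit vectors.

    The wrap runs with decreasing azimuth (clockwise seen from +z) while
    ascending in z: a left-handed superhelix with the dyad bp placed on
    the +y side.  Flexible terminal base pairs continue on straight
    tangential arms off the superhelix path.
    """
    n = spec.n_bp
    dyad_pos = (n - 1) // 2 if n % 2 == 1 else n // 2 - 1
    i = np.arange(n) - dyad_pos                       # bp index, 0 at dyad
    dphi = spec.wrap_turns * 2.0 * math.pi / max(n - 1, 1)
    phi = math.pi / 2.0 - i * dphi
    dz = spec.pitch * dphi / (2.0 * math.pi)
    centers = np.column_stack([spec.radius * np.cos(phi),
                               spec.radius * np.sin(phi),
                               i * dz])
    tangents = np.column_stack([spec.radius * np.sin(phi) * dphi,
                                -spec.radius * np.cos(phi) * dphi,
                                np.full(n, dz)])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    radial = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    binorm = np.cross(tangents, radial)
    # duplex pseudo-twist of the separation direction, one turn per 10.4 bp
    psi = i * (2.0 * math.pi / 10.4)
    sep = (np.cos(psi)[:, None] * radial + np.sin(psi)[:, None] * binorm)
    sep /= np.linalg.norm(sep, axis=1, keepdims=True)

    f = spec.flexible_bp_per_end
    if f > 0:
        arc = float(np.linalg.norm(centers[dyad_pos + 1] - centers[dyad_pos]))
        lo, hi = f, n - 1 - f
        for k in range(lo - 1, -1, -1):
            centers[k] = centers[lo] - (lo - k) * arc * tangents[lo]
            tangents[k] = tangents[lo]
            sep[k] = sep[lo]
        for k in range(hi + 1, n):
            centers[k] = centers[hi] + (k - hi) * arc * tangents[hi]
            tangents[k] = tangents[hi]
            sep[k] = sep[hi]
    return centers, tangents, sep


def _histone_sites(spec: NucleosomeSpec) -> list[np.ndarray]:
    """Placeholder pseudo-atom positions for the 8 histone chains,
    arranged on two rings inside the DNA gyres."""
    sites = []
    m = spec.histone_atoms_per_chain
    for h in range(8):
        z0 = -6.0 if h < 4 else 6.0
        a0 = math.radians(45.0 * h + (22.5 if h >= 4 else 0.0))
        pts = []
        for k in range(m):
            a = a0 + math.radians(4.0) * k
            r = 20.0 - 1.5 * (k % 3)
            pts.append([r * math.cos(a), r * math.sin(a), z0 + 0.8 * (k % 2)])
        sites.append(np.array(pts))
    return sites


_DNA_CHAINS = ("I", "J")
_HISTONE_CHAINS = ("A", "B", "C", "D", "E", "F", "G", "H")


def _nucleosome_atoms(spec: NucleosomeSpec, chain_prefix: str = ""
                      ) -> tuple[_AtomList, NucleosomeAnnotation]:
    centers, _tangents, sep = _superhelix_path(spec)
    n = spec.n_bp
    atoms = _AtomList()
    c1_1 = centers + 0.5 * spec.c1_separation * sep
    c1_2 = centers - 0.5 * spec.c1_separation * sep
    s1, s2 = (chain_prefix + c for c in _DNA_CHAINS)
    # strand 1: residues 1..n in 5'->3' order along the path
    for j in range(n):
        atoms.add(s1, j + 1, "DA", "C1'", "C", c1_1[j])
    # strand 2 antiparallel: its residue r pairs strand-1 residue n+1-r
    for r in range(1, n + 1):
        atoms.add(s2, r, "DT", "C1'", "C", c1_2[n - r])
    histones: dict[str, str] = {}
    for h, pts in enumerate(_histone_sites(spec)):
        ident = HISTONE_ORDER[h % 4]
        if ident == "H3":
            ident = spec.variant
        cid = chain_prefix + _HISTONE_CHAINS[h]
        histones[cid] = ident
        for k, p in enumerate(pts):
            atoms.add(cid, k + 1, "ALA", "CA", "C", p)
    ann = NucleosomeAnnotation("N1", (s1, s2), histones,
                               flexible_bp_per_end=spec.flexible_bp_per_end)
    return atoms, ann


def build_nucleosome(spec: NucleosomeSpec | None = None) -> AnnotatedComplex:
    """One idealized nucleosome at the canonical pose.

    294 C1′ atoms for the default 147-bp spec, dyad on +y, superhelical
    axis along +z.  Flexible terminal base pairs (CENP-A preset: 13 per
    end, leaving 121 stably bound) are displaced onto straight arms off
    the superhelix and flagged not stably bound.  Deterministic: equal
    specs give identical coordinates.
    """
    spec = spec or NucleosomeSpec()
    atoms, ann = _nucleosome_atoms(spec)
    return AnnotatedComplex(atoms.to_model(), [ann])


def _transform_atoms(atoms: _AtomList, tf: RigidTransform) -> None:
    for i, p in enumerate(atoms.xyz):
        atoms.xyz[i] = tf.rotation @ p + tf.translation


def _factor_atoms(chain: str, specific_targets: list[np.ndarray],
                  neighbor_targets: list[np.ndarray],
                  specific_out: list[np.ndarray],
                  neighbor_out: list[np.ndarray]) -> _AtomList:
    """Placeholder bridging-factor chain.

    Residues 100–101 sit 3.2 Å from histone / DNA atoms of the specific
    nucleosome; residues 102–117 follow the neighbor's DNA with the
    basic α6-face residues 3.2 Å outside the anchored C1′ atoms.
    """
    atoms = _AtomList()
    for rid, (tgt, out) in enumerate(zip(specific_targets, specific_out), start=100):
        atoms.add(chain, rid, "ALA", "CA", "C", tgt + 3.2 * out)
    basic = sorted(ALPHA6_BASIC_RESIDUES)
    positions: dict[int, np.ndarray] = {}
    outward: dict[int, np.ndarray] = {}
    for (tgt, out), rid in zip(zip(neighbor_targets, neighbor_out), basic):
        positions[rid] = tgt + 3.2 * out
        outward[rid] = out
    # non-basic helix residues interpolate between their basic neighbors
    # and sit 2 A further off the DNA (helix backbone vs basic face)
    for rid in range(102, 118):
        if rid in positions:
            continue
        lower = max(b for b in basic if b < rid)
        upper = min(b for b in basic if b > rid)
        w = (rid - lower) / (upper - lower)
        out = _safe_unit((1 - w) * outward[lower] + w * outward[upper],
                         fallback=np.array([0.0, 0.0, 1.0]))
        positions[rid] = ((1 - w) * positions[lower] + w * positions[upper]
                          + 2.0 * out)
    for rid in range(102, 118):
        name = ALPHA6_BASIC_RESIDUES.get(rid, "ALA")
        atoms.add(chain, rid, name, "CA", "C", positions[rid])
    return atoms


def _safe_unit(v: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else fallback


def _outward(point: np.ndarray, origin: np.ndarray, z: np.ndarray) -> np.ndarray:
    """In-disc radial unit vector from the nucleosome origin through ``point``."""
    d = point - origin
    d = d - (d @ z) * z
    return _safe_unit(d, fallback=np.array([1.0, 0.0, 0.0]))


def _c1_position(complex_: AnnotatedComplex, nucleosome_id: str, bp_index: int,
                 strand: int = 0) -> np.ndarray:
    from .frames import pair_base_steps  # local import to avoid cycle at import time

    series = pair_base_steps(complex_, nucleosome_id)
    pos = series.position_of(bp_index)
    return (series.c1_strand1 if strand == 0 else series.c1_strand2)[pos]


def _neighbor_anchor_bps(anchor: int, count: int = 6) -> list[int]:
    """bp indices for the basic-face contacts, spread outward from the
    dyad so every |SHL| stays inside the anchor's unit bin."""
    s = 1 if anchor >= 0 else -1
    return [anchor + s * d for d in range(-2, count - 2)]


def _check_anchor(anchor: int, nuc_spec: NucleosomeSpec) -> None:
    lo = -((nuc_spec.n_bp - 1) // 2) + nuc_spec.flexible_bp_per_end
    hi = (nuc_spec.n_bp - 1) // 2 if nuc_spec.n_bp % 2 == 1 else nuc_spec.n_bp // 2
    hi -= nuc_spec.flexible_bp_per_end
    for bp in _neighbor_anchor_bps(anchor):
        if bp < lo or bp > hi:
            raise SpecError(
                f"factor anchor bp {bp} outside the stably wrapped range "
                f"[{lo}, {hi}]")


def build_stack(spec: StackSpec | None = None,
                nuc_spec: NucleosomeSpec | None = None) -> AnnotatedComplex:
    """Two nucleosomes related by an exact ground-truth step, with 0, 1
    or 2 bridging-factor placeholder chains.

    Factor 1 contacts histone and DNA atoms of nucleosome ``N1`` (the
    specific partner) and DNA-only atoms of ``N2`` at the anchored SHL;
    factor 2, when present, is the mirrored copy (specific on ``N2``,
    DNA-only on ``N1``).  ``step_parameters`` on the two reference frames
    returns the ground-truth step to numerical precision.
    """
    spec = spec or StackSpec()
    nuc_spec = nuc_spec or NucleosomeSpec()
    _check_anchor(spec.neighbor_anchor_bp, nuc_spec)

    atoms1, ann1 = _nucleosome_atoms(nuc_spec, chain_prefix="")
    ann1.nucleosome_id = "N1"
    base = AnnotatedComplex(atoms1.to_model(), [ann1])
    frame1 = nucleosome_frame(base, "N1")
    tf = step_to_transform(frame1, spec.step)

    atoms2, ann2 = _nucleosome_atoms(nuc_spec, chain_prefix="")
    _transform_atoms(atoms2, tf)
    rename = dict(zip(("I", "J", *_HISTONE_CHAINS),
                      ("K", "L", "M", "N", "O", "P", "Q", "R", "S", "T")))
    atoms2.chain = [rename[c] for c in atoms2.chain]
    ann2 = NucleosomeAnnotation(
        "N2", (rename["I"], rename["J"]),
        {rename[c]: h for c, h in ann2.histones.items()},
        flexible_bp_per_end=ann2.flexible_bp_per_end)

    combined = _AtomList()
    combined.extend(atoms1)
    combined.extend(atoms2)
    model = combined.to_model()
    complex_ = AnnotatedComplex(model, [ann1, ann2])

    factors: list[FactorAnnotation] = []
    factor_atoms = _AtomList()
    pairs = [("U", "N1", "N2")]
    if spec.n_factors == 2:
        pairs.append(("V", "N2", "N1"))
    if spec.n_factors >= 1:
        for chain, spec_id, nb_id in pairs:
            fa = _place_factor(complex_, chain, spec_id, nb_id,
                               spec.specific_anchor_bp, spec.neighbor_anchor_bp)
            factor_atoms.extend(fa)
            factors.append(FactorAnnotation(f"F_{chain}", chain, "CENP-N"))

    combined.extend(factor_atoms)
    return AnnotatedComplex(combined.to_model(), [ann1, ann2], factors)


def _place_factor(complex_: AnnotatedComplex, chain: str, specific_id: str,
                  neighbor_id: str, specific_anchor_bp: int,
                  neighbor_anchor_bp: int) -> _AtomList:
    frame_s = nucleosome_frame(complex_, specific_id)
    frame_n = nucleosome_frame(complex_, neighbor_id)
    struct = complex_.structure
    nuc_s = complex_.nucleosome(specific_id)
    hist_chain = next(iter(nuc_s.histones))
    hist_idx = struct.atom_indices(chain=hist_chain)[0]
    hist_pos = struct.coords[0, hist_idx]
    dna_pos = _c1_position(complex_, specific_id, specific_anchor_bp)
    specific_targets = [hist_pos, dna_pos]
    specific_out = [_outward(hist_pos, frame_s.origin, frame_s.z),
                    _outward(dna_pos, frame_s.origin, frame_s.z)]
    neighbor_targets = []
    neighbor_out = []
    for bp in _neighbor_anchor_bps(neighbor_anchor_bp):
        p = _c1_position(complex_, neighbor_id, bp)
        neighbor_targets.append(p)
        neighbor_out.append(_outward(p, frame_n.origin, frame_n.z))
    return _factor_atoms(chain, specific_targets, neighbor_targets,
                         specific_out, neighbor_out)


def build_fiber(spec: FiberSpec | None = None,
                nuc_spec: NucleosomeSpec | None = None) -> AnnotatedComplex:
    """Helical nucleosomal array with exact per-nucleosome rise/twist.

    Nucleosome *k* sits at azimuth ``k * twist`` on a cylinder of the
    given radius, ``k * rise`` along the fiber axis, its disc tilted off
    the axis by ``disc_tilt``; the reference-frame origins therefore lie
    exactly on a circular helix.  Terminal nucleosomes within
    ``terminal_flexible_count`` of either end are flagged flexible.
    Bridging factors (0/1/2 per step) connect nucleosome *k* (specific)
    to the DNA of nucleosome *k+2* at the anchored SHL.
    """
    spec = spec or FiberSpec()
    nuc_spec = nuc_spec or NucleosomeSpec()
    if spec.factors_per_step:
        _check_anchor(spec.neighbor_anchor_bp, nuc_spec)
        _check_anchor(-spec.neighbor_anchor_bp, nuc_spec)

    base_atoms, _ = _nucleosome_atoms(nuc_spec)
    base = AnnotatedComplex(base_atoms.to_model(), [
        NucleosomeAnnotation("base", ("I", "J"), {},
                             flexible_bp_per_end=nuc_spec.flexible_bp_per_end)])
    frame0 = nucleosome_frame(base, "base")
    B = frame0.rotation

    combined = _AtomList()
    annotations: list[NucleosomeAnnotation] = []
    from scipy.spatial.transform import Rotation

    n = spec.n_nucleosomes
    for k in range(n):
        az = math.radians(spec.twist_per_nucleosome * k)
        origin = np.array([spec.fiber_radius * math.cos(az),
                           spec.fiber_radius * math.sin(az),
                           spec.rise_per_nucleosome * k])
        R_target = (Rotation.from_euler("z", spec.twist_per_nucleosome * k,
                                        degrees=True).as_matrix()
                    @ Rotation.from_euler("x", spec.disc_tilt,
                                          degrees=True).as_matrix())
        R = R_target @ B.T
        t = origin - R @ frame0.origin
        atoms_k, ann_k = _nucleosome_atoms(nuc_spec, chain_prefix=f"n{k}")
        _transform_atoms(atoms_k, RigidTransform(R, t))
        ann_k.nucleosome_id = f"N{k}"
        ann_k.flexible = (k < spec.terminal_flexible_count
                          or k >= n - spec.terminal_flexible_count)
        combined.extend(atoms_k)
        annotations.append(ann_k)

    complex_ = AnnotatedComplex(combined.to_model(), annotations)
    factors: list[FactorAnnotation] = []
    factor_atoms = _AtomList()
    if spec.factors_per_step:
        for k in range(n - 2):
            anchors = [spec.neighbor_anchor_bp, -spec.neighbor_anchor_bp]
            for copy_i in range(spec.factors_per_step):
                chain = f"f{k}_{copy_i}"
                fa = _place_factor(complex_, chain, f"N{k}", f"N{k + 2}",
                                   -25, anchors[copy_i])
                factor_atoms.extend(fa)
                factors.append(FactorAnnotation(f"F{k}_{copy_i}", chain, "CENP-N"))
    combined.extend(factor_atoms)
    return AnnotatedComplex(combined.to_model(), annotations, factors)


def sample_ensemble(base: AnnotatedComplex, dispersion: DispersionSpec
                    ) -> TrajectoryEnsemble:
    """Jittered ensemble around a base structure.

    Nucleosome 1 (first annotation) is held fixed; every frame perturbs
    nucleosome 2's frame with independent Gaussian noise on each step
    parameter, then optionally adds iid coordinate jitter to all mobile
    atoms (everything except nucleosome 1).  Because the reference
    nucleosome never moves, the result is flagged as aligned on it.
    Identical spec + seed give identical ensembles.
    """
    if len(base.nucleosomes) < 2:
        raise SpecError("ensemble sampling needs at least 2 nucleosomes")
    rng = np.random.default_rng(dispersion.seed)
    id1 = base.nucleosomes[0].nucleosome_id
    id2 = base.nucleosomes[1].nucleosome_id
    f1 = nucleosome_frame(base, id1)
    f2 = nucleosome_frame(base, id2)
    base_step = step_parameters(f1, f2)
    *_, base_phase = _decompose(f1.rotation, f1.origin, f2.rotation, f2.origin)

    struct = base.structure
    nuc1 = base.nucleosomes[0]
    fixed_chains = set(nuc1.dna_chains) | set(nuc1.histones)
    mobile_mask = ~np.isin(struct.chain_ids, list(fixed_chains))
    nuc2 = base.nucleosomes[1]
    nuc2_idx = struct.atom_indices(chain=list(nuc2.dna_chains) + list(nuc2.histones))

    base_coords = struct.coords[0]
    frames = np.tile(base_coords, (dispersion.n_frames, 1, 1))
    R2, O2 = f2.rotation, f2.origin
    for fi in range(dispersion.n_frames):
        dr = rng.normal(0.0, dispersion.sigma_rise) if dispersion.sigma_rise else 0.0
        dx = rng.normal(0.0, dispersion.sigma_shift) if dispersion.sigma_shift else 0.0
        dy = rng.normal(0.0, dispersion.sigma_shift) if dispersion.sigma_shift else 0.0
        dt = rng.normal(0.0, dispersion.sigma_tilt) if dispersion.sigma_tilt else 0.0
        dw = rng.normal(0.0, dispersion.sigma_twist) if dispersion.sigma_twist else 0.0
        if dr or dx or dy or dt or dw:
            tilt = abs(base_step.tilt + dt)
            if tilt > 180.0:
                tilt = 360.0 - tilt
            twist = (base_step.twist + dw + 180.0) % 360.0 - 180.0
            if twist == -180.0:
                twist = 180.0
            step = StackStep(base_step.rise + dr, base_step.shift_x + dx,
                             base_step.shift_y + dy, tilt, twist)
            tf_new = step_to_transform(f1, step, hinge_phase=base_phase)
            new_frame = f1.transformed(tf_new.rotation, tf_new.translation)
            Rm = new_frame.rotation @ R2.T
            tm = new_frame.origin - Rm @ O2
            frames[fi, nuc2_idx] = base_coords[nuc2_idx] @ Rm.T + tm
        if dispersion.coordinate_jitter > 0:
            jitter = rng.normal(0.0, dispersion.coordinate_jitter,
                                size=(int(mobile_mask.sum()), 3))
            frames[fi, mobile_mask] += jitter
    return TrajectoryEnsemble(base, frames, aligned_on=id1)


def write_fixture(obj: AnnotatedComplex | TrajectoryEnsemble,
                  path: str | Path, roles_path: str | Path | None = None,
                  format: str = "auto") -> None:
    """Write a built complex or ensemble plus its role-map sidecar.

    Complexes go to PDB or mmCIF (by extension); ensembles to
    multi-model PDB.  The YAML sidecar (default ``<path>.roles.yaml``)
    re-annotates the file identically via :func:`~nucstack.structio.assign_roles`.
    """
    path = Path(path)
    roles_path = Path(roles_path) if roles_path else path.with_suffix(
        path.suffix + ".roles.yaml")
    if isinstance(obj, TrajectoryEnsemble):
        topo = obj.topology
        model = topo.structure.with_coords(obj.frames)
        write_structure(model, path, format=format)
        save_role_map(role_map_of(topo), roles_path)
    elif isinstance(obj, AnnotatedComplex):
        write_structure(obj.structure, path, format=format)
        save_role_map(role_map_of(obj), roles_path)
    else:
        raise SpecError(f"cannot write object of type {type(obj).__name__}")
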