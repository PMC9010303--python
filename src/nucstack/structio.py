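"""Atomic-model I/O and chain-role annotation.

Structures are held in a flat, array-backed :class:`StructureModel`:
one topology (chain / residue / atom identifiers) plus one coordinate set
per model.  Multi-model files become trajectory ensembles over a shared
topology.  Biological roles (which chains form a nucleosome's DNA wrap,
which are histones, which are bridging factors such as CENP-N) are never
guessed from sequence; they are assigned explicitly from a role map,
usually a small YAML sidecar shipped next to each model.

Coordinates are in Angstrom throughout; residue indices are taken as
given in the file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .errors import (
    AnnotationError,
    EmptyStructureError,
    TopologyError,
    ValidationError,
)

HISTONE_IDENTITIES = frozenset({"H3", "CENP-A", "H4", "H2A", "H2B"})

__all__ = [
    "StructureModel",
    "NucleosomeAnnotation",
    "FactorAnnotation",
    "AnnotatedComplex",
    "TrajectoryEnsemble",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "assign_roles",
    "load_role_map",
    "save_role_map",
    "write_records",
]


@dataclass
class StructureModel:
    """Flat atom table plus one or more coordinate sets.

    ``coords`` has shape ``(model_count, n_atoms, 3)``; all identifier
    arrays have length ``n_atoms`` and describe every model identically.
    """

    chain_ids: np.ndarray          # dtype=object (str)
    residue_indices: np.ndarray    # int
    residue_names: np.ndarray      # str
    atom_names: np.ndarray         # str
    elements: np.ndarray           # str, e.g. "C", "N", "P"
    coords: np.ndarray             # (model_count, n_atoms, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (models, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        n = self.coords.shape[1]
        for name in ("chain_ids", "residue_indices", "residue_names",
                     "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} length {arr.shape} != atom count {n}")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def model_count(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def atom_indices(
        self,
        chain: str | Sequence[str] | None = None,
        atom_name: str | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching the given filters, in file order."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            wanted = {chain} if isinstance(chain, str) else set(chain)
            mask &= np.isin(self.chain_ids, list(wanted))
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        if heavy_only:
            mask &= ~np.isin(self.elements, ["H", "D"])
        return np.nonzero(mask)[0]

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Same topology, new coordinate set(s)."""
        return StructureModel(
            self.chain_ids, self.residue_indices, self.residue_names,
            self.atom_names, self.elements, np.asarray(coords, dtype=float),
        )


@dataclass
class NucleosomeAnnotation:
    nucleosome_id: str
    dna_chains: tuple[str, str]
    histones: dict[str, str] = field(default_factory=dict)  # chain -> identity
    flexible_bp_per_end: int = 0
    flexible: bool = False  # whole nucleosome too disordered for geometry fits


@dataclass
class FactorAnnotation:
    factor_id: str
    chain_id: str
    label: str = "CENP-N"


@dataclass
class AnnotatedComplex:
    """A structure plus the biological grouping of its chains."""

    structure: StructureModel
    nucleosomes: list[NucleosomeAnnotation]
    factors: list[FactorAnnotation] = field(default_factory=list)

    def nucleosome(self, nucleosome_id: str) -> NucleosomeAnnotation:
        for nuc in self.nucleosomes:
            if nuc.nucleosome_id == nucleosome_id:
                return nuc
        raise AnnotationError(f"unknown nucleosome id {nucleosome_id!r}")

    def factor(self, factor_id: str) -> FactorAnnotation:
        for fac in self.factors:
            if fac.factor_id == factor_id:
                return fac
        raise AnnotationError(f"unknown factor id {factor_id!r}")

    def chain_nucleosome(self) -> dict[str, tuple[str, str]]:
        """chain id -> (nucleosome id, 'DNA'|'histone') for annotated chains."""
        out: dict[str, tuple[str, str]] = {}
        for nuc in self.nucleosomes:
            for c in nuc.dna_chains:
                out[c] = (nuc.nucleosome_id, "DNA")
            for c in nuc.histones:
                out[c] = (nuc.nucleosome_id, "histone")
        return out

    def with_coords(self, coords: np.ndarray) -> "AnnotatedComplex":
        return AnnotatedComplex(self.structure.with_coords(coords),
                                self.nucleosomes, self.factors)


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames over one annotated topology."""

    topology: AnnotatedComplex
    frames: np.ndarray                    # (n_frames, n_atoms, 3)
    aligned_on: str | None = None         # nucleosome id frames are aligned on

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.structure.n_atoms:
            raise TopologyError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.structure.n_atoms}")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    def frame_complex(self, i: int) -> AnnotatedComplex:
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# gemmi conversion
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, path: str) -> StructureModel:
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    chain_ids: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coord_sets: list[np.ndarray] = []

    first_key: list[tuple[str, int, str]] | None = None
    for mi, model in enumerate(st):
        xyz: list[tuple[float, float, float]] = []
        key: list[tuple[str, int, str]] = []
        for chain in model:
            for res in chain:
                for atom in res:
                    key.append((chain.name, res.seqid.num, atom.name))
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    if mi == 0:
                        chain_ids.append(chain.name)
                        res_idx.append(res.seqid.num)
                        res_names.append(res.name)
                        atom_names.append(atom.name)
                        elements.append(atom.element.name)
        if first_key is None:
            first_key = key
        elif key != first_key:
            raise TopologyError(
                f"model {mi + 1} of {path} does not match model 1 topology "
                f"({len(key)} vs {len(first_key)} atoms or differing identities)")
        coord_sets.append(np.array(xyz, dtype=float))

    if not chain_ids:
        raise EmptyStructureError(f"no atoms in {path}")
    return StructureModel(
        np.array(chain_ids, dtype=object),
        np.array(res_idx, dtype=int),
        np.array(res_names, dtype=object),
        np.array(atom_names, dtype=object),
        np.array(elements, dtype=object),
        np.stack(coord_sets),
    )


def _to_gemmi(model: StructureModel, name: str = "nucstack") -> gemmi.Structure:
    # gemmi's add_chain/add_residue copy their argument, so each container
    # must be fully populated before being added to its parent.
    st = gemmi.Structure()
    st.name = name
    for mi in range(model.model_count):
        gm = gemmi.Model(mi + 1)
        chains: list[gemmi.Chain] = []
        res: gemmi.Residue | None = None
        prev = (None, None)
        for ai in range(model.n_atoms):
            cid = str(model.chain_ids[ai])
            rid = int(model.residue_indices[ai])
            if not chains or cid != chains[-1].name:
                if res is not None:
                    chains[-1].add_residue(res)
                    res = None
                chains.append(gemmi.Chain(cid))
                prev = (None, None)
            if prev != (cid, rid):
                if res is not None:
                    chains[-1].add_residue(res)
                res = gemmi.Residue()
                res.name = str(model.residue_names[ai])
                res.seqid = gemmi.SeqId(rid, " ")
                prev = (cid, rid)
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[ai])
            atom.element = gemmi.Element(str(model.elements[ai]))
            x, y, z = model.coords[mi, ai]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            assert res is not None
            res.add_atom(atom)
        if res is not None:
            chains[-1].add_residue(res)
        for ch in chains:
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF model file into a :class:`StructureModel`.

    ``format`` may be ``pdb``, ``mmcif`` or ``auto`` (extension-based).
    Multi-model files yield ``model_count > 1``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        st = gemmi.read_structure(str(path))
    elif format == "pdb":
        st = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
    else:
        raise ValidationError(f"unknown format {format!r}")
    return _from_gemmi(st, str(path))


def read_trajectory(path: str | Path,
                    role_map: Mapping[str, Any] | None = None,
                    ) -> TrajectoryEnsemble:
    """Read a multi-model file as a trajectory ensemble.

    Frames are ordered as in the file; every model must share one
    topology (a :class:`~nucstack.errors.TopologyError` names the first
    offending model otherwise).  ``role_map`` attaches chain-role
    annotation; without it the ensemble has no nucleosome/factor
    annotation and only raw-coordinate operations apply.
    """
    model = read_structure(path)
    topo = assign_roles(model.with_coords(model.coords[0]), role_map or {})
    return TrajectoryEnsemble(topo, model.coords)


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> None:
    """Write a structure (or multi-model ensemble) as PDB or mmCIF."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = _to_gemmi(model)
    if format == "pdb":
        for cid in model.chains:
            if len(cid) > 2:
                raise ValidationError(
                    f"chain id {cid!r} too long for PDB; write mmCIF instead")
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# role maps
# ---------------------------------------------------------------------------

def assign_roles(structure: StructureModel,
                 role_map: Mapping[str, Any]) -> AnnotatedComplex:
    """Group chains of ``structure`` into nucleosomes and factors.

    ``role_map`` is the parsed form of the YAML sidecar::

        nucleosomes:
          - id: N1
            dna: [I, J]
            histones: {A: H3, B: H4, C: H2A, D: H2B, ...}
            flexible_bp_per_end: 0
            flexible: false
        factors:
          - {id: F1, chain: K, label: CENP-N}

    Chains not mentioned are retained in the structure but ignored by all
    analyses.  Raises :class:`AnnotationError` for a nucleosome without
    exactly two DNA chains or for chains absent from the structure, and
    :class:`ValidationError` for unknown histone identities.
    """
    known = set(structure.chains)
    nucleosomes: list[NucleosomeAnnotation] = []
    seen_ids: set[str] = set()
    for entry in role_map.get("nucleosomes", []):
        nid = str(entry["id"])
        if nid in seen_ids:
            raise AnnotationError(f"duplicate nucleosome id {nid!r}")
        seen_ids.add(nid)
        dna = [str(c) for c in entry.get("dna", [])]
        if len(dna) != 2:
            raise AnnotationError(
                f"nucleosome {nid!r} must have exactly 2 DNA chains, got {len(dna)}")
        histones = {str(c): str(h) for c, h in (entry.get("histones") or {}).items()}
        for c, h in histones.items():
            if h not in HISTONE_IDENTITIES:
                raise ValidationError(
                    f"unknown histone identity {h!r} for chain {c!r} "
                    f"(allowed: {sorted(HISTONE_IDENTITIES)})")
        for c in [*dna, *histones]:
            if c not in known:
                raise AnnotationError(
                    f"chain {c!r} of nucleosome {nid!r} not in structure")
        nucleosomes.append(NucleosomeAnnotation(
            nid, (dna[0], dna[1]), histones,
            int(entry.get("flexible_bp_per_end", 0)),
            bool(entry.get("flexible", False)),
        ))

    factors: list[FactorAnnotation] = []
    for entry in role_map.get("factors", []) or []:
        fid = str(entry["id"])
        chain = str(entry["chain"])
        if chain not in known:
            raise AnnotationError(f"factor chain {chain!r} not in structure")
        factors.append(FactorAnnotation(fid, chain, str(entry.get("label", "factor"))))

    return AnnotatedComplex(structure, nucleosomes, factors)


def role_map_of(complex_: AnnotatedComplex) -> dict[str, Any]:
    """The role map (plain dict) that reproduces this annotation."""
    return {
        "nucleosomes": [
            {
                "id": nuc.nucleosome_id,
                "dna": list(nuc.dna_chains),
                "histones": dict(nuc.histones),
                "flexible_bp_per_end": nuc.flexible_bp_per_end,
                "flexible": nuc.flexible,
            }
            for nuc in complex_.nucleosomes
        ],
        "factors": [
            {"id": f.factor_id, "chain": f.chain_id, "label": f.label}
            for f in complex_.factors
        ],
    }


def load_role_map(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"role map {path} is not a mapping")
    return data


def save_role_map(role_map: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(role_map), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# tabular records
# ---------------------------------------------------------------------------

def _records_frame(records: Any) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValidationError("empty record table")
        return records
    records = list(records)
    if not records:
        raise ValidationError("empty record list")
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, Mapping):
            rows.append(dict(r))
        else:
            raise ValidationError(f"unsupported record type {type(r).__name__}")
    cols = list(rows[0])
    for r in rows:
        if list(r) != cols:
            raise ValidationError("records have heterogeneous fields")
    return pd.DataFrame(rows, columns=cols)


def write_records(records: Iterable[Any] | pd.DataFrame, path: str | Path,
                  format: str = "csv") -> None:
    """Write analysis records as CSV or JSON with fixed column order and
    fixed float precision (6 decimals), so identical inputs give
    byte-identical output."""
    df = _records_frame(records)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.6f")
    elif format == "json":
        def clean(v: Any) -> Any:
            if isinstance(v, (np.floating, float)):
                return round(float(v), 6)
            if isinstance(v, np.integer):
                return int(v)
            return v
        payload = [{k: clean(v) for k, v in row.items()}
                   for row in df.to_dict(orient="records")]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown record format {format!r}")
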