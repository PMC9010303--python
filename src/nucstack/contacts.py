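"""Factor–nucleosome contacts, occupancy and bridge classification.

A *contact* is a heavy-atom pair (one atom on a bridging factor, one on
an annotated nucleosome) within a distance cutoff; the default 4.5 Å is
a conventional heavy-atom contact radius and is always recorded in the
output.  A factor *bridges* when its contacts reach two nucleosomes:
the partner receiving histone contacts is the specifically recognized
nucleosome, the partner receiving DNA-only contacts is the neighbor.
Neighbor-DNA contacts are mapped through the base-pair series to
continuous superhelical locations, giving the SHL span and per-bin
counts that characterize where the factor's basic helix docks
(SHL 4–5 for mononucleosome stacks, SHL 6–7 in fibers).

Neighbor search uses a KD-tree at the cutoff radius; the result is
contractually identical to the all-pairs computation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AnnotationError, GapError, SelectionError, ValidationError
from .frames import BP_PER_SHL, BasePairSeries
from .structio import AnnotatedComplex, TrajectoryEnsemble

DEFAULT_CUTOFF = 4.5            # heavy-atom contact cutoff, A
STRONG_OCCUPANCY_THRESHOLD = 0.5

__all__ = [
    "ContactRecord",
    "BridgeInterface",
    "SHLContactMap",
    "find_contacts",
    "contact_occupancy",
    "classify_bridge",
    "map_contacts_to_shl",
]


@dataclass(frozen=True)
class ContactRecord:
    """One factor-atom / nucleosome-atom pair within the cutoff."""

    factor_id: str
    factor_chain: str
    factor_resid: int
    factor_resname: str
    factor_atom: str
    nucleosome_id: str
    target_kind: str          # "DNA" | "histone"
    target_chain: str
    target_resid: int
    target_atom: str
    distance: float


@dataclass
class BridgeInterface:
    """Which nucleosomes a factor engages, and how."""

    factor_id: str
    specific_nucleosome_ids: list[str]   # histone-contacting partners
    neighbor_nucleosome_ids: list[str]   # DNA-only partners
    is_bridge: bool
    ambiguous: bool                      # >1 histone-contacting partner
    per_residue_counts: dict[int, int]   # factor residue -> contact count

    @property
    def specific_nucleosome_id(self) -> str | None:
        return self.specific_nucleosome_ids[0] if self.specific_nucleosome_ids else None

    @property
    def neighbor_nucleosome_id(self) -> str | None:
        return self.neighbor_nucleosome_ids[0] if self.neighbor_nucleosome_ids else None


@dataclass
class SHLContactMap:
    """Neighbor-DNA contacts resolved by superhelical location."""

    nucleosome_id: str
    shl_values: np.ndarray               # continuous SHL per contact
    span: tuple[float, float] | None     # (min, max) of |SHL|; None if empty
    bin_counts: dict[int, int]           # half-open |SHL| bin [k, k+1) -> count
    status: str = "ok"                   # "ok" | "no neighbor contacts"

    @property
    def empty(self) -> bool:
        return self.span is None


def _coords_or_frame(complex_: AnnotatedComplex,
                     coords: np.ndarray | None) -> np.ndarray:
    return complex_.structure.coords[0] if coords is None else coords


def find_contacts(complex_: AnnotatedComplex, cutoff: float = DEFAULT_CUTOFF,
                  coords: np.ndarray | None = None) -> list[ContactRecord]:
    """All heavy-atom factor/nucleosome contacts within ``cutoff``.

    Every qualifying atom pair is reported exactly once; hydrogens are
    excluded on both sides.  Raises
    :class:`~nucstack.errors.AnnotationError` when no factor chains are
    annotated and :class:`~nucstack.errors.ValidationError` for a
    non-positive cutoff.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if not complex_.factors:
        raise AnnotationError("no factor chains annotated")
    struct = complex_.structure
    xyz = _coords_or_frame(complex_, coords)
    chain_roles = complex_.chain_nucleosome()
    target_idx = struct.atom_indices(chain=list(chain_roles), heavy_only=True)
    records: list[ContactRecord] = []
    if len(target_idx) == 0:
        return records
    tree = cKDTree(xyz[target_idx])
    for factor in complex_.factors:
        fac_idx = struct.atom_indices(chain=factor.chain_id, heavy_only=True)
        if len(fac_idx) == 0:
            continue
        neighbors = tree.query_ball_point(xyz[fac_idx], r=cutoff)
        for fi, hits in zip(fac_idx, neighbors):
            for h in hits:
                ti = target_idx[h]
                dist = float(np.linalg.norm(xyz[fi] - xyz[ti]))
                nuc_id, kind = chain_roles[str(struct.chain_ids[ti])]
                records.append(ContactRecord(
                    factor_id=factor.factor_id,
                    factor_chain=str(struct.chain_ids[fi]),
                    factor_resid=int(struct.residue_indices[fi]),
                    factor_resname=str(struct.residue_names[fi]),
                    factor_atom=str(struct.atom_names[fi]),
                    nucleosome_id=nuc_id,
                    target_kind=kind,
                    target_chain=str(struct.chain_ids[ti]),
                    target_resid=int(struct.residue_indices[ti]),
                    target_atom=str(struct.atom_names[ti]),
                    distance=dist,
                ))
    records.sort(key=lambda r: (r.factor_chain, r.factor_resid, r.factor_atom,
                                r.target_chain, r.target_resid, r.target_atom))
    return records


PairKey = tuple[str, int, str, int]  # factor chain, resid, target chain, resid


def contact_occupancy(ensemble: TrajectoryEnsemble,
                      cutoff: float = DEFAULT_CUTOFF,
                      pair_selection: Callable[[ContactRecord], bool] | None = None,
                      strong_threshold: float = STRONG_OCCUPANCY_THRESHOLD,
                      ) -> pd.DataFrame:
    """Per residue-pair contact occupancy over an ensemble.

    Occupancy is the fraction of frames in which a (factor residue,
    target residue) pair has at least one heavy-atom contact within the
    cutoff; pairs at or above ``strong_threshold`` are labelled strong.
    ``pair_selection`` filters contact records before aggregation; a
    selection that matches nothing raises
    :class:`~nucstack.errors.SelectionError`.
    """
    n = ensemble.frame_count
    seen: Counter[PairKey] = Counter()
    meta: dict[PairKey, ContactRecord] = {}
    matched_any = False
    for i in range(n):
        frame_pairs: set[PairKey] = set()
        for rec in find_contacts(ensemble.topology, cutoff,
                                 coords=ensemble.frames[i]):
            if pair_selection is not None and not pair_selection(rec):
                continue
            matched_any = True
            key = (rec.factor_chain, rec.factor_resid,
                   rec.target_chain, rec.target_resid)
            frame_pairs.add(key)
            meta.setdefault(key, rec)
        seen.update(frame_pairs)
    if pair_selection is not None and not matched_any:
        raise SelectionError("pair selection matched no contacts in any frame")
    rows = []
    for key in sorted(seen):
        rec = meta[key]
        occ = seen[key] / n
        rows.append({
            "factor_chain": key[0], "factor_resid": key[1],
            "factor_resname": rec.factor_resname,
            "target_chain": key[2], "target_resid": key[3],
            "nucleosome_id": rec.nucleosome_id, "target_kind": rec.target_kind,
            "occupancy": occ, "strong": occ >= strong_threshold,
        })
    return pd.DataFrame(rows, columns=[
        "factor_chain", "factor_resid", "factor_resname", "target_chain",
        "target_resid", "nucleosome_id", "target_kind", "occupancy", "strong"])


def classify_bridge(contacts: Sequence[ContactRecord], factor_id: str
                    ) -> BridgeInterface:
    """Classify one factor's contacts into specific vs neighbor partners.

    The specific partner receives histone contacts; any partner touched
    only through DNA is a neighbor.  Contacting histones of more than
    one nucleosome is flagged ambiguous (all partners listed).  A factor
    with no contacts yields an empty, non-bridging interface.
    """
    mine = [c for c in contacts if c.factor_id == factor_id]
    histone_nucs: list[str] = []
    all_nucs: list[str] = []
    per_res: Counter[int] = Counter()
    for c in mine:
        if c.nucleosome_id not in all_nucs:
            all_nucs.append(c.nucleosome_id)
        if c.target_kind == "histone" and c.nucleosome_id not in histone_nucs:
            histone_nucs.append(c.nucleosome_id)
        per_res[c.factor_resid] += 1
    neighbors = [n for n in all_nucs if n not in histone_nucs]
    return BridgeInterface(
        factor_id=factor_id,
        specific_nucleosome_ids=histone_nucs,
        neighbor_nucleosome_ids=neighbors,
        is_bridge=len(all_nucs) >= 2,
        ambiguous=len(histone_nucs) > 1,
        per_residue_counts=dict(per_res),
    )


def map_contacts_to_shl(contacts: Sequence[ContactRecord],
                        neighbor_series: BasePairSeries) -> SHLContactMap:
    """Map neighbor-DNA contacts onto superhelical locations.

    Each DNA contact targeting the series' nucleosome is mapped to its
    base-pair index and then to continuous SHL (bp / 10.4); the span is
    the [min, max] of |SHL| and counts fall into half-open unit bins
    [k, k+1) on |SHL|.  A contact residue absent from the series raises
    :class:`~nucstack.errors.GapError`.
    """
    nuc_id = neighbor_series.nucleosome_id
    dna_chains = {neighbor_series.strand1_chain, neighbor_series.strand2_chain}
    shls: list[float] = []
    for c in contacts:
        if c.nucleosome_id != nuc_id or c.target_kind != "DNA":
            continue
        if c.target_chain not in dna_chains:
            raise GapError(
                f"contact chain {c.target_chain!r} not a strand of {nuc_id!r}")
        bp = neighbor_series.bp_index_of_residue(c.target_chain, c.target_resid)
        shls.append(bp / BP_PER_SHL)
    if not shls:
        return SHLContactMap(nuc_id, np.array([]), None, {},
                             status="no neighbor contacts")
    values = np.array(shls)
    abs_vals = np.abs(values)
    bins = Counter(int(np.floor(v)) for v in abs_vals)
    return SHLContactMap(nuc_id, values,
                         (float(abs_vals.min()), float(abs_vals.max())),
                         dict(sorted(bins.items())))
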