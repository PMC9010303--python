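import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nucstack.contacts import (
    classify_bridge,
    contact_occupancy,
    find_contacts,
    map_contacts_to_shl,
)
from nucstack.errors import AnnotationError, SelectionError, ValidationError
from nucstack.frames import pair_base_steps
from nucstack.structio import (
    AnnotatedComplex,
    FactorAnnotation,
    NucleosomeAnnotation,
    TrajectoryEnsemble,
)
from nucstack.synth import DispersionSpec, StackSpec, build_fiber, build_stack, fiber_preset, sample_ensemble

from conftest import make_model, random_contact_complex


def brute_force_pairs(complex_, cutoff):
    """O(n^2) oracle: every heavy factor/nucleosome atom pair <= cutoff."""
    struct = complex_.structure
    xyz = struct.coords[0]
    roles = complex_.chain_nucleosome()
    tgt = struct.atom_indices(chain=list(roles), heavy_only=True)
    out = set()
    for fac in complex_.factors:
        fidx = struct.atom_indices(chain=fac.chain_id, heavy_only=True)
        if len(fidx) == 0 or len(tgt) == 0:
            continue
        D = cdist(xyz[fidx], xyz[tgt])
        for a, b in zip(*np.nonzero(D <= cutoff)):
            out.add((int(fidx[a]), int(tgt[b])))
    return out


def record_pairs(complex_, records):
    struct = complex_.structure
    key = {}
    for i in range(struct.n_atoms):
        key[(str(struct.chain_ids[i]), int(struct.residue_indices[i]),
             str(struct.atom_names[i]))] = i
    return {(key[(r.factor_chain, r.factor_resid, r.factor_atom)],
             key[(r.target_chain, r.target_resid, r.target_atom)])
            for r in records}


class TestFindContacts:
    def test_single_pair_at_known_distance(self):
        model = make_model({
            "F": [(1, "LYS", "NZ", "N", (0.0, 0.0, 0.0))],
            "D1": [(1, "DA", "P", "P", (3.0, 0.0, 0.0)),
                   (2, "DA", "P", "P", (10.0, 0.0, 0.0))],
            "D2": [(1, "DT", "P", "P", (0.0, 20.0, 0.0))],
        })
        cx = AnnotatedComplex(model, [NucleosomeAnnotation("n", ("D1", "D2"))],
                              [FactorAnnotation("f", "F")])
        recs = find_contacts(cx, 4.5)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.0)
        assert recs[0].target_kind == "DNA" and recs[0].nucleosome_id == "n"

    @pytest.mark.parametrize("cutoff", [3.5, 4.0, 4.5, 5.0])
    def test_matches_brute_force_on_random_complexes(self, cutoff):
        rng = np.random.default_rng(int(cutoff * 10))
        for _ in range(5):
            cx = random_contact_complex(rng, n_atoms=400)
            got = record_pairs(cx, find_contacts(cx, cutoff))
            assert got == brute_force_pairs(cx, cutoff)

    def test_hydrogens_excluded(self):
        rng = np.random.default_rng(8)
        cx = random_contact_complex(rng, n_atoms=300, hydrogen_fraction=0.5)
        for rec in find_contacts(cx, 5.0):
            struct = cx.structure
            fi = (struct.chain_ids == rec.factor_chain) & \
                (struct.residue_indices == rec.factor_resid)
            assert "H" not in set(struct.elements[fi])

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(11)
        cx = random_contact_complex(rng, n_atoms=300)
        prev = set()
        for cutoff in (3.5, 4.0, 4.5, 5.0):
            cur = record_pairs(cx, find_contacts(cx, cutoff))
            assert prev <= cur
            prev = cur

    def test_requires_factor_annotation_and_positive_cutoff(self, bare_stack):
        with pytest.raises(AnnotationError):
            find_contacts(bare_stack, 4.5)
        stack = build_stack()
        with pytest.raises(ValidationError):
            find_contacts(stack, 0.0)


class TestOccupancy:
    def _constructed_ensemble(self, in_contact_frames, n_frames=20):
        """Factor atom near DNA in chosen frames, far otherwise."""
        model = make_model({
            "F": [(1, "LYS", "NZ", "N", (0.0, 0.0, 0.0))],
            "D1": [(1, "DA", "P", "P", (3.0, 0.0, 0.0))],
            "D2": [(1, "DT", "P", "P", (0.0, 30.0, 0.0))],
        })
        cx = AnnotatedComplex(model, [NucleosomeAnnotation("n", ("D1", "D2"))],
                              [FactorAnnotation("f", "F")])
        frames = np.repeat(model.coords, n_frames, axis=0)
        for i in range(n_frames):
            if i not in in_contact_frames:
                frames[i, 0] = [50.0, 50.0, 50.0]
        return TrajectoryEnsemble(cx, frames)

    def test_full_and_fractional_occupancy(self):
        always = self._constructed_ensemble(set(range(20)))
        occ = contact_occupancy(always, 4.5)
        assert occ.occupancy.tolist() == [1.0]
        assert bool(occ.strong.iloc[0])
        partial = self._constructed_ensemble({0, 2, 4, 6, 8, 10, 12})
        occ = contact_occupancy(partial, 4.5)
        assert occ.occupancy.tolist() == [0.35]
        assert not bool(occ.strong.iloc[0])

    def test_empty_selection_raises(self):
        ens = self._constructed_ensemble(set(range(20)))
        with pytest.raises(SelectionError):
            contact_occupancy(ens, 4.5, pair_selection=lambda r: False)

    def test_occupancy_non_increasing_with_jitter(self, mono_stack):
        """A seeded jitter ladder degrades mean contact occupancy."""
        means = []
        for sigma in (0.0, 1.0, 2.5):
            ens = sample_ensemble(mono_stack, DispersionSpec(
                n_frames=15, seed=13, coordinate_jitter=sigma))
            occ = contact_occupancy(ens, 4.5)
            means.append(occ.occupancy.mean())
        assert means[0] >= means[1] >= means[2]

    def test_occupancy_monotone_in_cutoff(self, mono_stack):
        ens = sample_ensemble(mono_stack, DispersionSpec(
            n_frames=10, seed=21, coordinate_jitter=1.0))
        occ_small = contact_occupancy(ens, 4.0).set_index(
            ["factor_resid", "target_chain", "target_resid"])
        occ_large = contact_occupancy(ens, 5.0).set_index(
            ["factor_resid", "target_chain", "target_resid"])
        common = occ_small.index.intersection(occ_large.index)
        assert len(common) > 0
        assert (occ_small.loc[common, "occupancy"]
                <= occ_large.loc[common, "occupancy"] + 1e-12).all()


class TestBridgeClassification:
    def test_mono_stack_preset(self, mono_stack):
        recs = find_contacts(mono_stack, 4.5)
        bridge = classify_bridge(recs, "F_U")
        assert bridge.is_bridge
        assert bridge.specific_nucleosome_ids == ["N1"]
        assert bridge.neighbor_nucleosome_ids == ["N2"]
        assert not bridge.ambiguous

    def test_two_factor_stack_finds_two_bridges(self):
        stack = build_stack(StackSpec(n_factors=2))
        recs = find_contacts(stack, 4.5)
        bu = classify_bridge(recs, "F_U")
        bv = classify_bridge(recs, "F_V")
        assert bu.is_bridge and bv.is_bridge
        assert bv.specific_nucleosome_ids == ["N2"]
        assert bv.neighbor_nucleosome_ids == ["N1"]

    def test_single_nucleosome_contacts_are_not_a_bridge(self):
        model = make_model({
            "F": [(1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
                  (2, "ARG", "NH1", "N", (0.0, 3.0, 0.0))],
            "D1": [(1, "DA", "P", "P", (3.0, 0.0, 0.0))],
            "D2": [(1, "DT", "P", "P", (40.0, 0.0, 0.0))],
            "H": [(1, "ALA", "CA", "C", (0.0, 6.0, 0.0))],
        })
        cx = AnnotatedComplex(
            model, [NucleosomeAnnotation("n1", ("D1", "D2"), {"H": "H3"})],
            [FactorAnnotation("f", "F")])
        bridge = classify_bridge(find_contacts(cx, 4.5), "f")
        assert not bridge.is_bridge
        assert bridge.specific_nucleosome_ids == ["n1"]

    def test_histone_contacts_on_both_partners_flagged_ambiguous(self):
        model = make_model({
            "F": [(1, "LYS", "NZ", "N", (0.0, 0.0, 0.0))],
            "D1": [(1, "DA", "P", "P", (90.0, 0.0, 0.0))],
            "D2": [(1, "DT", "P", "P", (90.0, 5.0, 0.0))],
            "H1": [(1, "ALA", "CA", "C", (3.0, 0.0, 0.0))],
            "D3": [(1, "DA", "P", "P", (90.0, 10.0, 0.0))],
            "D4": [(1, "DT", "P", "P", (90.0, 15.0, 0.0))],
            "H2": [(1, "ALA", "CA", "C", (0.0, 3.0, 0.0))],
        })
        cx = AnnotatedComplex(
            model,
            [NucleosomeAnnotation("n1", ("D1", "D2"), {"H1": "H3"}),
             NucleosomeAnnotation("n2", ("D3", "D4"), {"H2": "H3"})],
            [FactorAnnotation("f", "F")])
        bridge = classify_bridge(find_contacts(cx, 4.5), "f")
        assert bridge.ambiguous
        assert set(bridge.specific_nucleosome_ids) == {"n1", "n2"}

    def test_factor_with_no_contacts_gives_empty_interface(self, mono_stack):
        bridge = classify_bridge([], "F_U")
        assert not bridge.is_bridge and bridge.specific_nucleosome_id is None


class TestSHLMapping:
    def test_known_bp_indices_map_to_expected_span(self, nucleosome):
        series = pair_base_steps(nucleosome, "N1")
        # contacts at bp 44 and 50 (strand-1 resids 118 and 124)
        recs = []
        for bp in (44, 50):
            resid = int(series.strand1_resids[series.position_of(bp)])
            recs.append(_dna_record(series, resid))
        smap = map_contacts_to_shl(recs, series)
        assert smap.span == pytest.approx((44 / 10.4, 50 / 10.4))
        assert smap.bin_counts == {4: 2}

    def test_mono_stack_preset_maps_to_bin_4_5(self, mono_stack):
        recs = find_contacts(mono_stack, 4.5)
        series = pair_base_steps(mono_stack, "N2")
        smap = map_contacts_to_shl(
            [c for c in recs if c.factor_id == "F_U"], series)
        assert not smap.empty
        assert set(smap.bin_counts) == {4}
        assert 4.0 <= smap.span[0] <= smap.span[1] < 5.0

    def test_fiber_preset_maps_to_bin_6_7(self):
        fiber = build_fiber(fiber_preset("cenpn_like"))
        recs = find_contacts(fiber, 4.5)
        series = pair_base_steps(fiber, "N2")
        own = [c for c in recs if c.factor_id == "F0_0"]
        bridge = classify_bridge(own, "F0_0")
        assert bridge.specific_nucleosome_ids == ["N0"]
        assert bridge.neighbor_nucleosome_ids == ["N2"]
        smap = map_contacts_to_shl(own, series)
        assert set(smap.bin_counts) == {6}
        assert 6.0 <= smap.span[0] <= smap.span[1] < 7.0

    def test_empty_contact_list_reports_status(self, nucleosome):
        series = pair_base_steps(nucleosome, "N1")
        smap = map_contacts_to_shl([], series)
        assert smap.empty and smap.status == "no neighbor contacts"


def _dna_record(series, resid):
    from nucstack.contacts import ContactRecord

    return ContactRecord("f", "F", 102, "LYS", "CA", series.nucleosome_id,
                         "DNA", series.strand1_chain, resid, "C1'", 3.0)
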