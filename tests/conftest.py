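import numpy as np
import pytest

from nucstack.structio import (
    AnnotatedComplex,
    FactorAnnotation,
    NucleosomeAnnotation,
    StructureModel,
)
from nucstack.synth import StackSpec, build_nucleosome, build_stack


@pytest.fixture(scope="session")
def nucleosome():
    """Default 147-bp idealized nucleosome."""
    return build_nucleosome()


@pytest.fixture(scope="session")
def mono_stack():
    """Default bridged two-nucleosome stack (one factor)."""
    return build_stack()


@pytest.fixture(scope="session")
def bare_stack():
    """Two stacked nucleosomes without any bridging factor."""
    return build_stack(StackSpec(n_factors=0))


def make_model(chains):
    """Tiny StructureModel from {chain: [(resid, resname, atom, element, xyz)]}."""
    cid, rid, rnm, anm, elt, xyz = [], [], [], [], [], []
    for chain, atoms in chains.items():
        for (r, rn, a, e, p) in atoms:
            cid.append(chain)
            rid.append(r)
            rnm.append(rn)
            anm.append(a)
            elt.append(e)
            xyz.append(p)
    return StructureModel(
        np.array(cid, dtype=object), np.array(rid, dtype=int),
        np.array(rnm, dtype=object), np.array(anm, dtype=object),
        np.array(elt, dtype=object), np.array(xyz, dtype=float)[None])


def random_contact_complex(rng, n_atoms=500, box=40.0, hydrogen_fraction=0.1):
    """Random atom soup annotated as one nucleosome + one factor chain."""
    chains = np.array(["F", "D1", "D2", "H"], dtype=object)[
        rng.integers(0, 4, size=n_atoms)]
    elements = np.where(rng.random(n_atoms) < hydrogen_fraction, "H",
                        np.array(["C", "N", "O", "P"], dtype=object)[
                            rng.integers(0, 4, size=n_atoms)])
    model = StructureModel(
        chains,
        np.arange(n_atoms),
        np.full(n_atoms, "UNK", dtype=object),
        np.array([f"X{i % 9}" for i in range(n_atoms)], dtype=object),
        elements.astype(object),
        (rng.random((n_atoms, 3)) * box)[None],
    )
    return AnnotatedComplex(
        model,
        [NucleosomeAnnotation("nuc", ("D1", "D2"), {"H": "H3"})],
        [FactorAnnotation("fac", "F")],
    )


def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return R.as_matrix(), rng.normal(scale=30.0, size=3)
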