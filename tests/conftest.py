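import numpy as np
import pytest

from toxinterface import synth
from toxinterface.core_io import Atom, Selection, Structure


def make_atom(serial, coords, element="C", name=None, res_seq=1, chain="A",
              res_name="ALA", model_id=1):
    from toxinterface.core_io import element_mass
    name = name or element
    return Atom(serial=serial, name=name, element=element,
                mass=element_mass(element), res_name=res_name,
                res_seq=res_seq, chain_id=chain,
                coords=np.asarray(coords, dtype=float), model_id=model_id)


def brute_force_np_pairs(atoms_a, atoms_b, cutoff=6.0):
    """O(n^2) heavy-atom pair count: the independent contact oracle."""
    count = 0
    for a in atoms_a:
        if a.is_hydrogen:
            continue
        for b in atoms_b:
            if b.is_hydrogen:
                continue
            if np.linalg.norm(a.coords - b.coords) <= cutoff:
                count += 1
    return count


@pytest.fixture
def toy_complex():
    spec = synth.ToyComplexSpec(
        n_res_per_chain=10, chains=("A", "B"),
        planted_contacts=(("A", 2, "B", 3), ("A", 5, "B", 7), ("A", 9, "B", 1)),
        seed=7)
    return synth.build_toy_complex(spec)


@pytest.fixture
def chain_selections():
    return Selection.make(chains="A"), Selection.make(chains="B")


def random_cloud(n, rng, box=20.0, chain="A", res_seq=1, serial0=1):
    return [make_atom(serial0 + i, rng.uniform(0, box, 3), chain=chain,
                      res_seq=res_seq) for i in range(n)]
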