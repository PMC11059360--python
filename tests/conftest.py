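import numpy as np
import pytest

from slc26kit.io import Atom, Structure


@pytest.fixture
def make_atom():
    """Factory for quick ad-hoc atoms."""
    counter = {"n": 0}

    def _make(pos, name=None, element="C", resname="ALA", resseq=None,
              chain="A", vdw=1.7, hetero=False):
        counter["n"] += 1
        return Atom(
            serial=counter["n"],
            name=name or f"C{counter['n']}",
            element=element,
            residue_name=resname,
            residue_seq=resseq if resseq is not None else counter["n"],
            chain_id=chain,
            position=np.asarray(pos, float),
            vdw_radius=vdw,
            is_hetero=hetero,
        )

    return _make


@pytest.fixture
def make_structure():
    """Structure factory: atoms named C1..Cn at residues 1..n."""

    def _make(positions, resname="ALA", chain="A", element="C", vdw=1.7,
              one_residue=False):
        atoms = [
            Atom(serial=i + 1, name=f"C{i + 1}", element=element,
                 residue_name=resname,
                 residue_seq=1 if one_residue else i + 1,
                 chain_id=chain, position=np.asarray(p, float),
                 vdw_radius=vdw, is_hetero=False)
            for i, p in enumerate(positions)
        ]
        return Structure(atoms)

    return _make


def random_rotation(rng):
    """Uniform random rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
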