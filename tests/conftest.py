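import numpy as np
import pytest

from abrkit.fixtures import FixtureSpec, generate_family
from abrkit.model import AbrConsensus
from abrkit.structure_io import Atom, Chain, ComplexStructure, Residue


def random_complex(rng: np.random.Generator, n_ab: int = 10,
                   n_ag: int = 10, box: float = 12.0) -> ComplexStructure:
    """A complex with uniformly random atom positions in a small box,
    dense enough that contacts occur by chance (for oracle tests)."""
    def chain(cid, n, offset):
        residues = []
        for i in range(n):
            atoms = tuple(
                Atom(name, tuple(rng.uniform(0, box, 3) + offset))
                for name in ("CA", "CB", "CG")[: int(rng.integers(1, 4))]
            )
            aa = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
            residues.append(Residue(cid, i + 1, "", aa, atoms))
        return Chain(cid, residues)

    return ComplexStructure(
        "rnd", chain("H", n_ab, 0.0), chain("L", n_ab, 2.0),
        chain("G", max(n_ag, 5), 4.0))


def brute_force_pairs(cx: ComplexStructure, cutoff: float):
    """All-atom-pairs contact oracle (O(n^2) distance scan)."""
    pairs = set()
    for role in ("heavy", "light"):
        for i, res in enumerate(cx.chain(role)):
            for j, ag in enumerate(cx.antigen):
                d = min(
                    float(np.linalg.norm(a.xyz - b.xyz))
                    for a in res.atoms for b in ag.atoms)
                if d <= cutoff:
                    pairs.add((role, i, j))
    return pairs


def rigid_transform_structure(cx: ComplexStructure,
                              rng: np.random.Generator) -> ComplexStructure:
    """Apply one random proper rotation + translation to every atom."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)

    def move(chain: Chain) -> Chain:
        out = []
        for r in chain:
            atoms = tuple(
                Atom(a.name, tuple(R @ a.xyz + t), a.occupancy, a.altloc)
                for a in r.atoms)
            out.append(Residue(r.chain_id, r.number, r.icode, r.aa, atoms))
        return Chain(chain.chain_id, out)

    return ComplexStructure(cx.pdb_id, move(cx.heavy), move(cx.light),
                            move(cx.antigen))


@pytest.fixture(scope="session")
def family():
    return generate_family(FixtureSpec(seed=7), n=12)


@pytest.fixture(scope="session")
def fitted_model(family):
    return AbrConsensus().fit([m.structure for m in family.members])
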