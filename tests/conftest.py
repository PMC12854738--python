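import numpy as np
import pytest

from ktnkit.synthetic_data import build_helix_fixture

DUPLEX_SEQ = "GGGAGCGCUCCC"
DUPLEX_PAIRS = [(i, len(DUPLEX_SEQ) + 1 - i) for i in range(1, 7)]


@pytest.fixture(scope="session")
def duplex():
    """Idealised 6-bp A-form duplex with known cWW pairing."""
    structure, truth = build_helix_fixture(DUPLEX_SEQ, DUPLEX_PAIRS)
    return structure, truth


def make_atom_structure(atom_specs):
    """Arbitrary point-cloud structure for geometric tests.

    ``atom_specs``: list of (resseq, atom_name, element, xyz) tuples; each
    residue becomes a generic 'LIG' residue.
    """
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("pts")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    current = None
    serial = 1
    for resseq, name, element, xyz in atom_specs:
        if resseq != current:
            sb.init_residue("LIG", " ", resseq, " ")
            current = resseq
        sb.init_atom(name, np.asarray(xyz, dtype=np.float32), 0.0, 1.0, " ",
                     name, serial, element=element)
        serial += 1
    return sb.get_structure()


def minimax_merge_oracle(ktn):
    """Exact pairwise minimax path energies by Kruskal union-find.

    Independent of the superbasin/tree machinery: processing transition
    states in ascending energy, two minima's minimax merge energy is the
    energy of the edge that first joins their components.
    """
    parent = {m.id: m.id for m in ktn.minima}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merge = {}
    groups = {m.id: {m.id} for m in ktn.minima}
    for ts in sorted(ktn.edges(), key=lambda t: t.V):
        ra, rb = find(ts.min1), find(ts.min2)
        if ra == rb:
            continue
        for a in groups[ra]:
            for b in groups[rb]:
                merge[(min(a, b), max(a, b))] = ts.V
        parent[rb] = ra
        groups[ra] |= groups.pop(rb)
    return merge
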