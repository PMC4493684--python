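import numpy as np
import pytest

from mlppi.structure_io import ContactMap, ProteinChain


def atom_line(serial, name, resname, chain, resseq, xyz, altloc=" ",
              element=None, record="ATOM"):
    """One fixed-column PDB ATOM/HETATM record."""
    element = element or name[0]
    padded = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (f"{record:<6s}{serial:>5d} {padded}{altloc}{resname:>3s} "
            f"{chain}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n")


@pytest.fixture
def two_chain_pdb(tmp_path):
    """A PDB file with two 5-residue chains facing each other."""
    lines = []
    serial = 1
    for k in range(5):
        lines.append(atom_line(serial, "CA", "ALA", "A", k + 1,
                               (3.0 * k, 0.0, 0.0)))
        serial += 1
    for k in range(5):
        lines.append(atom_line(serial, "CA", "GLY", "B", k + 1,
                               (3.0 * k, 3.5, 0.0)))
        serial += 1
    path = tmp_path / "two_chain.pdb"
    path.write_text("".join(lines) + "END\n")
    return path


def point_chain(chain_id, points, sequence=None, ss3=None):
    """Chain with one single-atom residue per 3D point."""
    coords = [np.array([p], dtype=float) for p in points]
    seq = sequence or "A" * len(points)
    return ProteinChain(chain_id, seq, ss3 or "", coords)


def random_contact_map(rng, n_a=60, n_b=60, n_contacts=30,
                       a_id="p", b_id="q"):
    contacts = set()
    while len(contacts) < n_contacts:
        contacts.add((rng.randrange(n_a), rng.randrange(n_b)))
    return ContactMap(a_id, b_id, contacts, n_a, n_b)


def random_graph_edges(rng, n_vertices, edge_prob):
    names = [f"v{k:02d}" for k in range(n_vertices)]
    edges = [(a, b) for i, a in enumerate(names)
             for b in names[i + 1:] if rng.random() < edge_prob]
    return names, edges
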