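"""Reading protein structures/sequences and deriving residue contact maps.

The residue-level ground truth for the whole pipeline is geometric: two
residues from two *different* chains are "in contact" when any pair of their
heavy atoms lies within a Euclidean distance cutoff (4 Angstrom by default).
Secondary structure is handled in the reduced 3-state alphabet E (sheet),
H (helix), C (coil); 8-state DSSP strings are reduced with the conventional
mapping and structural gaps become coil.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

logger = logging.getLogger("mlppi")

#: one-letter codes of the 20 standard amino acids, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default DSSP 8-state -> 3-state reduction; gaps ('-' or ' ') become coil
DSSP_REDUCTION = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C",
}

DEFAULT_CONTACT_CUTOFF = 4.0  # Angstrom, inclusive


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class ProteinChain:
    """A single protein chain: sequence, 3-state structure, optional coordinates.

    ``coords`` holds one array of heavy-atom 3D points (shape (n_atoms, 3), in
    Angstrom) per residue; a residue may have an empty atom list. Residues are
    indexed 0-based and contiguously.
    """

    chain_id: str
    sequence: str
    ss3: str = ""
    coords: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.ss3:
            self.ss3 = "C" * len(self.sequence)
        if len(self.ss3) != len(self.sequence):
            raise ValueError(
                f"chain {self.chain_id}: ss3 length {len(self.ss3)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.coords is not None and len(self.coords) != len(self.sequence):
            raise ValueError(
                f"chain {self.chain_id}: {len(self.coords)} coordinate "
                f"entries for {len(self.sequence)} residues"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactMap:
    """Set of inter-chain residue index pairs in 3D contact."""

    chain_a_id: str
    chain_b_id: str
    contacts: set[tuple[int, int]] = field(default_factory=set)
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (0 <= i < self.n_a and 0 <= j < self.n_b):
                raise ValueError(f"contact ({i}, {j}) out of range "
                                 f"({self.n_a} x {self.n_b})")

    def transpose(self) -> "ContactMap":
        return ContactMap(
            self.chain_b_id, self.chain_a_id,
            {(j, i) for i, j in self.contacts}, self.n_b, self.n_a,
        )

    def __len__(self) -> int:
        return len(self.contacts)


# ---------------------------------------------------------------------------
# PDB reading

def read_chains(path: str | Path, resolution_max: float | None = None) -> list[ProteinChain]:
    """Read all protein chains (with heavy-atom coordinates) from a PDB file.

    Only standard amino-acid residues are kept; hydrogens are dropped and for
    disordered atoms the first altloc is used. Chains without any standard
    residue are skipped with a warning. ``ss3`` is initialised to all-coil;
    supply real secondary structure separately (``read_ss3``/``reduce_ss``).

    If ``resolution_max`` is given and the file header reports a worse
    (larger) resolution, an empty list is returned with a warning.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    if resolution_max is not None:
        res = structure.header.get("resolution")
        if res is not None and res > resolution_max:
            logger.warning("%s: resolution %.2f exceeds maximum %.2f; skipping",
                           path, res, resolution_max)
            return []

    chains: list[ProteinChain] = []
    model = next(structure.get_models())
    for chain in model:
        seq_chars: list[str] = []
        res_coords: list[np.ndarray] = []
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " ":
                continue  # water / HETATM
            resname = residue.get_resname()
            one = protein_letters_3to1.get(resname)
            if one is None or len(one) != 1:
                one = "X" if resname else None
            if one is None:
                continue
            atoms = []
            for atom in residue:
                if atom.element == "H":
                    continue
                # first altloc only: Bio.PDB disordered atoms expose the
                # selected (first) position by default
                atoms.append(atom.get_coord())
            seq_chars.append(one if one in AMINO_ACIDS else "X")
            res_coords.append(np.asarray(atoms, dtype=float).reshape(-1, 3))
        if not seq_chars:
            logger.warning("chain %s of %s has no standard residues; skipped",
                           chain.id, path)
            continue
        chains.append(ProteinChain(chain.id, "".join(seq_chars), coords=res_coords))
    return chains


# ---------------------------------------------------------------------------
# Secondary structure

def reduce_ss(ss8: str, mapping: dict[str, str] | None = None) -> str:
    """Reduce an 8-state DSSP string (gaps included) to the E/H/C alphabet.

    H, G, I -> H; E, B -> E; everything else, including gap symbols, -> C.
    """
    table = DSSP_REDUCTION if mapping is None else mapping
    out = []
    for pos, ch in enumerate(ss8):
        try:
            out.append(table[ch])
        except KeyError:
            raise ValueError(
                f"unknown secondary-structure symbol {ch!r} at position {pos}"
            ) from None
    return "".join(out)


# ---------------------------------------------------------------------------
# Contact maps

def contact_map(a: ProteinChain, b: ProteinChain,
                cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactMap:
    """All residue pairs of two chains with any heavy-atom distance <= cutoff.

    Residues with empty atom lists are never in contact. The relation is
    symmetric: swapping the chains transposes the contact set.
    """
    if a.coords is None or b.coords is None:
        raise ValueError("both chains need per-residue coordinates")
    if a.chain_id == b.chain_id and a is b:
        raise ValueError("contact map requires two distinct chains")

    # flatten atoms, remember owning residue, query once with a KD-tree
    pts_a, owner_a = _flatten(a.coords)
    pts_b, owner_b = _flatten(b.coords)
    contacts: set[tuple[int, int]] = set()
    if len(pts_a) and len(pts_b):
        tree = cKDTree(pts_b)
        for ia, hits in enumerate(tree.query_ball_point(pts_a, cutoff)):
            for ib in hits:
                contacts.add((int(owner_a[ia]), int(owner_b[ib])))
    return ContactMap(a.chain_id, b.chain_id, contacts, len(a), len(b))


def _flatten(coords: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    pts, owner = [], []
    for idx, atoms in enumerate(coords):
        if len(atoms):
            pts.append(atoms)
            owner.append(np.full(len(atoms), idx))
    if not pts:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(pts), np.concatenate(owner)


# ---------------------------------------------------------------------------
# Flat-file formats

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercased sequence mapping."""
    from Bio import SeqIO

    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA file {path}: {exc}") from exc
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def read_ss3(path: str | Path) -> dict[str, str]:
    """Read plain two-line-per-record 3-state secondary structure text.

    Format mirrors FASTA: a ``>id`` line followed by one line over {E,H,C}.
    """
    out: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = ""
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: structure line "
                                      "before any >id header")
                bad = set(line) - set("EHC")
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid ss3 symbols {sorted(bad)}")
                out[name] += line
    return out


def write_ss3(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, ss in records.items():
            fh.write(f">{name}\n{ss}\n")


def write_contacts(cmap: ContactMap, path: str | Path) -> None:
    """Write a contact map as TSV (0-based residue indices)."""
    with open(path, "w") as fh:
        fh.write(f"# chains\t{cmap.chain_a_id}\t{cmap.chain_b_id}"
                 f"\t{cmap.n_a}\t{cmap.n_b}\t0-based\n")
        for i, j in sorted(cmap.contacts):
            fh.write(f"{i}\t{j}\n")


def read_contacts(path: str | Path) -> ContactMap:
    contacts: set[tuple[int, int]] = set()
    a_id = b_id = ""
    n_a = n_b = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if line.startswith("#"):
                if parts[0] == "# chains" and len(parts) >= 5:
                    a_id, b_id, n_a, n_b = (parts[1], parts[2],
                                            int(parts[3]), int(parts[4]))
                continue
            try:
                i, j = int(parts[0]), int(parts[1])
            except (IndexError, ValueError):
                raise FormatError(f"{path}:{lineno}: expected two integer "
                                  f"columns, got {line!r}") from None
            contacts.add((i, j))
    if not n_a and contacts:
        n_a = max(i for i, _ in contacts) + 1
        n_b = max(j for _, j in contacts) + 1
    return ContactMap(a_id, b_id, contacts, n_a, n_b)
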