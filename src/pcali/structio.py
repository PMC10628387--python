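"""Structure and alignment I/O.

Reads single-chain protein structures from PDB files, derives heavy-atom
contact matrices and backbone-geometry secondary structure, groups
near-identical sequences, and provides the FASTA/manifest/substitution-matrix
readers and writers used by the rest of the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

GAP = "-"

#: residues are kept only if they have a C-alpha atom; heavy atoms exclude H/D
_HYDROGENS = {"H", "D"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass
class ProteinStructure:
    """One protein chain: sequence, coordinates, contacts, secondary structure.

    ``heavy_atoms[i]`` holds all non-hydrogen atom coordinates of residue
    ``i`` (Å); ``contacts`` is the symmetric binary heavy-atom contact
    matrix; ``sstruct`` is a string over ``{H, E, C}``.
    """

    id: str
    sequence: str
    calpha: np.ndarray
    heavy_atoms: list = field(default_factory=list)
    contacts: np.ndarray | None = None
    sstruct: str | None = None
    res_ids: list | None = None  # author residue numbering, for PDB output

    def __post_init__(self):
        self.calpha = np.asarray(self.calpha, dtype=float)
        L = len(self.sequence)
        if self.calpha.shape != (L, 3):
            raise ValueError(f"calpha shape {self.calpha.shape} != ({L}, 3)")
        if not np.all(np.isfinite(self.calpha)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        L = len(self)
        if self.contacts is not None:
            C = self.contacts
            if C.shape != (L, L):
                raise ValueError("contact matrix shape mismatch")
            if not np.array_equal(C, C.T) or np.any(np.diag(C)):
                raise ValueError("contacts must be symmetric with zero diagonal")
        if self.sstruct is not None and len(self.sstruct) != L:
            raise ValueError("sstruct length mismatch")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return ProteinStructure(
            id=self.id,
            sequence=self.sequence,
            calpha=self.calpha @ R.T + t,
            heavy_atoms=[np.asarray(a, float) @ R.T + t for a in self.heavy_atoms],
            contacts=self.contacts,
            sstruct=self.sstruct,
            res_ids=self.res_ids,
        )


@dataclass
class SequenceGroup:
    """Structures whose sequences differ by at most one substitution."""

    representative_id: str
    member_ids: list
    sequence: str


@dataclass
class Msa:
    """Multiple alignment: equal-length gapped rows keyed by ordered names."""

    names: list
    rows: list

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, k: int) -> str:
        return self.rows[k].replace(GAP, "")

    def row_of(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def drop_empty_columns(self) -> "Msa":
        keep = [c for c in range(self.ncols)
                if any(r[c] != GAP for r in self.rows)]
        return Msa(list(self.names), ["".join(r[c] for c in keep) for r in self.rows])

    def column_residue_indices(self) -> np.ndarray:
        """(n, ncols) residue index per cell, -1 at gaps."""
        out = np.full((len(self.rows), self.ncols), -1, dtype=int)
        for k, row in enumerate(self.rows):
            idx = 0
            for c, ch in enumerate(row):
                if ch != GAP:
                    out[k, c] = idx
                    idx += 1
        return out


# ---------------------------------------------------------------------------
# PDB reading

def read_structure(path, chain: str, cutoff: float = 4.5, min_sep: int = 3,
                   name: str | None = None) -> ProteinStructure:
    """Read one chain from a PDB file into a :class:`ProteinStructure`.

    Residues lacking a C-alpha are dropped (logged). Hydrogens, waters and
    heteroatoms are ignored; for disordered atoms the highest-occupancy
    location is kept; only the first model of multi-model files is used.
    Contacts and secondary structure are computed on the way in.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain not found: {chain!r} (file has {chain_ids})")

    seq, calpha, heavy, res_ids = [], [], [], []
    dropped = 0
    for res in model[chain]:
        if res.id[0] != " ":  # water / heteroatom records
            continue
        atoms = {}
        for atom in res:
            if atom.element in _HYDROGENS:
                continue
            # disordered atoms: Bio.PDB's selected child is highest occupancy
            atoms[atom.get_name()] = atom.coord
        if "CA" not in atoms:
            dropped += 1
            continue
        seq.append(_THREE_TO_ONE.get(res.get_resname(), "X"))
        calpha.append(atoms["CA"])
        heavy.append(np.array(list(atoms.values()), dtype=float))
        res_ids.append(res.id[1])
    if dropped:
        logger.warning("%s chain %s: dropped %d residue(s) without C-alpha",
                       path.name, chain, dropped)
    if not seq:
        raise ValueError(f"{path}: chain {chain} has no usable residues")

    s = ProteinStructure(
        id=name or f"{path.stem}{chain}",
        sequence="".join(seq),
        calpha=np.array(calpha, dtype=float),
        heavy_atoms=heavy,
        res_ids=res_ids,
    )
    s.contacts = compute_contacts(s, cutoff=cutoff, min_sep=min_sep)
    s.sstruct = assign_secondary_structure(s)
    return s


def compute_contacts(structure: ProteinStructure, cutoff: float = 4.5,
                     min_sep: int = 3) -> np.ndarray:
    """Binary residue contact matrix from heavy-atom proximity.

    ``contacts[i, j] = 1`` iff some heavy atom of residue *i* lies within
    ``cutoff`` Å of some heavy atom of residue *j* and ``|i - j| >= min_sep``.
    Near-diagonal pairs are excluded because trivially adjacent contacts
    carry no fold information.
    """
    L = len(structure)
    C = np.zeros((L, L), dtype=np.int8)
    coords, owner = [], []
    for i, atoms in enumerate(structure.heavy_atoms):
        atoms = np.asarray(atoms, float)
        if atoms.size == 0:
            logger.warning("%s residue %d has no heavy atoms", structure.id, i)
            continue
        coords.append(atoms)
        owner.extend([i] * len(atoms))
    if not coords:
        return C
    pts = np.vstack(coords)
    owner = np.asarray(owner)
    tree = cKDTree(pts)
    for a, b in tree.query_pairs(r=cutoff):
        i, j = owner[a], owner[b]
        if abs(i - j) >= min_sep:
            C[i, j] = C[j, i] = 1
    return C


# ---------------------------------------------------------------------------
# Secondary structure

# C-alpha distance windows for ideal geometries: an alpha-helix has
# d(i,i+2)≈5.4, d(i,i+3)≈5.1, d(i,i+4)≈6.2 Å; an extended strand has
# d(i,i+2)≈6.4-6.8 and d(i,i+3)≈9-10 Å.
_HELIX_D2 = (4.6, 6.0)
_HELIX_D3 = (4.3, 6.1)
_HELIX_D4 = (5.2, 7.0)
_STRAND_D2 = (5.9, 7.6)
_STRAND_D3 = (8.0, 11.5)
# consecutive C-alpha spacing must stay near the canonical ~3.8 Å for a
# helix window; tight turns (shorter virtual bonds) otherwise mimic helices
_HELIX_D1 = (3.2, 4.4)


def assign_secondary_structure(structure: ProteinStructure) -> str:
    """Assign H/E/C from C-alpha geometry alone.

    A window test on the i..i+2 / i..i+3 / i..i+4 distances (helix) and the
    i..i+2, i..i+3 distances (strand) labels the covered residues;
    helix wins over strand; everything else is coil. Chains shorter than 5
    residues are all coil. Deterministic for fixed coordinates; a DSSP
    string read with :func:`read_dssp_ss` may override it.
    """
    X = structure.calpha
    L = len(structure)
    if L < 5:
        return "C" * L
    d = lambda i, j: float(np.linalg.norm(X[j] - X[i]))
    ss = ["C"] * L
    for i in range(L - 3):
        d2, d3 = d(i, i + 2), d(i, i + 3)
        if _STRAND_D2[0] <= d2 <= _STRAND_D2[1] and _STRAND_D3[0] <= d3 <= _STRAND_D3[1]:
            for k in range(i, i + 4):
                ss[k] = "E"
    for i in range(L - 4):
        d2, d3, d4 = d(i, i + 2), d(i, i + 3), d(i, i + 4)
        if (_HELIX_D2[0] <= d2 <= _HELIX_D2[1]
                and _HELIX_D3[0] <= d3 <= _HELIX_D3[1]
                and _HELIX_D4[0] <= d4 <= _HELIX_D4[1]
                and all(_HELIX_D1[0] <= d(k, k + 1) <= _HELIX_D1[1]
                        for k in range(i, i + 4))):
            for k in range(i, i + 5):
                ss[k] = "H"
    return "".join(ss)


def read_dssp_ss(path, chain: str) -> str:
    """Extract an H/E/C string for one chain from a DSSP output file.

    DSSP classes are collapsed as H/G/I -> H, E/B -> E, everything else -> C.
    """
    out = []
    started = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("  #  RESIDUE"):
            started = True
            continue
        if not started or len(line) < 17:
            continue
        if line[13] == "!":  # chain break record
            continue
        if line[11] != chain:
            continue
        code = line[16]
        out.append("H" if code in "HGI" else "E" if code in "EB" else "C")
    if not out:
        raise ValueError(f"no DSSP records for chain {chain!r} in {path}")
    return "".join(out)


# ---------------------------------------------------------------------------
# Sequence grouping

def _hamming_le1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def group_sequences(structures) -> list:
    """Single-linkage grouping of structures whose sequences are identical
    within one point mutation (equal length, Hamming distance <= 1).

    The representative is the member with the most resolved residues
    (here: fewest 'X'), ties broken by lexicographic id. Output order
    follows the first appearance of each group in the input.
    """
    if not structures:
        raise ValueError("no structures to group")
    n = len(structures)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming_le1(structures[i].sequence, structures[j].sequence):
                parent[find(i)] = find(j)

    clusters: dict[int, list] = {}
    order = []
    for i in range(n):
        r = find(i)
        if r not in clusters:
            clusters[r] = []
            order.append(r)
        clusters[r].append(i)

    groups = []
    for r in order:
        members = clusters[r]
        def resolved(k):
            s = structures[k]
            return len(s.sequence) - s.sequence.count("X")
        rep = min(members, key=lambda k: (-resolved(k), structures[k].id))
        groups.append(SequenceGroup(
            representative_id=structures[rep].id,
            member_ids=[structures[k].id for k in members],
            sequence=structures[rep].sequence,
        ))
    return groups


# ---------------------------------------------------------------------------
# FASTA MSA / manifest / substitution matrix

def read_msa(path) -> Msa:
    names, rows = [], []
    cur = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            names.append(line[1:].split()[0])
            rows.append([])
            cur = rows[-1]
        else:
            if cur is None:
                raise ValueError(f"{path}: sequence data before first header")
            cur.append(line)
    if not names:
        raise ValueError(f"{path}: empty FASTA")
    rows = ["".join(r).upper().replace(".", GAP) for r in rows]
    return Msa(names, rows)


def write_msa(msa: Msa, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n")
            for k in range(0, len(row), width):
                fh.write(row[k:k + width] + "\n")


def read_manifest(path) -> list:
    """Parse a structure manifest: one ``path chain name`` triple per line
    ('#' starts a comment; name defaults to ``stem+chain``). Relative paths
    resolve against the manifest's directory."""
    base = Path(path).parent
    entries = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"bad manifest line: {raw!r}")
        p = Path(parts[0])
        if not p.is_absolute():
            p = base / p
        name = parts[2] if len(parts) == 3 else f"{p.stem}{parts[1]}"
        entries.append((p, parts[1], name))
    if not entries:
        raise ValueError(f"{path}: empty manifest")
    return entries


def read_substitution_matrix(path) -> dict:
    """Read an NCBI-format substitution matrix text file into a dict keyed by
    unordered residue pairs."""
    alphabet = None
    mat = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        if alphabet is None:
            alphabet = parts
            continue
        aa, vals = parts[0], parts[1:]
        for b, v in zip(alphabet, vals):
            mat[(aa, b)] = float(v)
    if alphabet is None:
        raise ValueError(f"{path}: no matrix content")
    return mat


def load_blosum62() -> dict:
    """BLOSUM62 as a pair-keyed dict (from biopython's bundled copy)."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return {(a, b): float(m[a, b]) for a in m.alphabet for b in m.alphabet}
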