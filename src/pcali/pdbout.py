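"""Minimal PDB writing: single chains and multi-MODEL superposed families.

Only the fields the readers in this package (and Bio.PDB) need are written.
Author residue numbering is preserved when the structure carries it.
"""

from __future__ import annotations

import numpy as np

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "U": "SEC", "O": "PYL",
}


def _atom_line(serial, name, resname, chain, resseq, xyz, element="C"):
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"ATOM  {serial:5d} {name_f} {resname:>3s} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}\n")


def _structure_records(structure, chain, rotation=None, translation=None):
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    serial = 1
    out = []
    for i, aa in enumerate(structure.sequence):
        resname = _ONE_TO_THREE.get(aa, "UNK")
        resseq = structure.res_ids[i] if structure.res_ids else i + 1
        atoms = np.asarray(structure.heavy_atoms[i], float) if i < len(structure.heavy_atoms) else structure.calpha[i][None, :]
        atoms = atoms @ R.T + t
        ca = np.asarray(structure.calpha[i], float) @ R.T + t
        out.append(_atom_line(serial, "CA", resname, chain, resseq, ca))
        serial += 1
        k = 1
        for a in atoms:
            if np.allclose(a, ca):
                continue
            out.append(_atom_line(serial, f"O{k}", resname, chain, resseq, a, element="O"))
            serial += 1
            k += 1
    out.append(f"TER   {serial:5d}\n")
    return out


def write_pdb(structure, path, chain: str = "A") -> None:
    with open(path, "w") as fh:
        fh.writelines(_structure_records(structure, chain))
        fh.write("END\n")


def write_superposed_pdb(structures, transforms, path) -> None:
    """One MODEL per structure with its rigid transform applied.

    ``transforms`` maps structure id to (rotation, translation)."""
    with open(path, "w") as fh:
        for m, s in enumerate(structures, start=1):
            R, t = transforms[s.id]
            fh.write(f"MODEL     {m:4d}\n")
            fh.write(f"REMARK 350 STRUCTURE {s.id}\n")
            fh.writelines(_structure_records(s, "A", R, t))
            fh.write("ENDMDL\n")
        fh.write("END\n")
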