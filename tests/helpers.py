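"""Shared test helpers: hand-rolled PDB text and tiny structures."""

import numpy as np

from condock.datatypes import ReceptorStructure, ResidueRecord


def pdb_line(serial, name, resname, chain, resseq, x, y, z, altloc=" ",
             occ=1.00, b=0.00, element=None, record="ATOM", icode=" "):
    """Format one fixed-width PDB coordinate line (independent of the
    package's own writer)."""
    element = element or name[0]
    name_field = f" {name:<3s}"[:4] if len(name) < 4 else name[:4]
    return (f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{b:6.2f}          {element:>2s}")


def ala_residue_lines(resseq, cx, cy, cz, chain="A", start_serial=1):
    """Five heavy-atom poly-alanine residue centered at (cx, cy, cz)."""
    offsets = [("N", "N", -1.2, 0.0, 0.0), ("CA", "C", 0.0, 0.0, 0.0),
               ("C", "C", 1.2, 0.0, 0.0), ("O", "O", 1.2, 1.2, 0.0),
               ("CB", "C", 0.0, -1.5, 0.0)]
    return [
        pdb_line(start_serial + i, name, "ALA", chain, resseq,
                 cx + dx, cy + dy, cz + dz, element=el)
        for i, (name, el, dx, dy, dz) in enumerate(offsets)
    ]


def three_residue_pdb():
    """A hand-written 3-residue poly-alanine receptor: 15 heavy atoms."""
    lines = []
    serial = 1
    for i in range(3):
        lines += ala_residue_lines(i + 1, 10.0 * i, 0.0, 0.0,
                                   start_serial=serial)
        serial += 5
    return "\n".join(lines) + "\nEND\n"


def water_lines(n, start_serial=100):
    return [
        pdb_line(start_serial + i, "O", "HOH", "A", 900 + i,
                 50.0 + i, 50.0, 50.0, element="O", record="HETATM")
        for i in range(n)
    ]


def make_structure(seq, spacing=8.0, chain="A"):
    """One-CA-atom-per-residue structure with the given one-letter
    sequence, residues spaced far apart along x."""
    from Bio.Data.IUPACData import protein_letters_1to3

    residues = []
    for i, c in enumerate(seq):
        name = protein_letters_1to3[c].upper() if c != "X" else "UNK"
        residues.append(ResidueRecord(
            (chain, i + 1, ""), name, ["C"],
            np.array([[i * spacing, 0.0, 0.0]])))
    return ReceptorStructure(residues)


def random_structure(rng, n_residues=50, box=30.0, max_atoms=4):
    """Residues with 1..max_atoms random heavy atoms in a cubic box."""
    residues = []
    for i in range(n_residues):
        n_atoms = int(rng.integers(1, max_atoms + 1))
        coords = rng.uniform(0.0, box, size=(n_atoms, 3))
        residues.append(ResidueRecord(("A", i + 1, ""), "ALA",
                                      ["C"] * n_atoms, coords))
    return ReceptorStructure(residues)


def brute_force_site(structure, pose, cutoff):
    """All-pairs O(N*M) contact oracle."""
    keys = set()
    for res in structure.residues:
        d = np.linalg.norm(res.coords[:, None, :] - pose.coords[None, :, :],
                           axis=2)
        if (d <= cutoff).any():
            keys.add(res.key)
    return frozenset(keys)
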