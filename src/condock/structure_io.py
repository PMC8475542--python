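"""Read and write receptor structures and docked-pose sets.

Receptors are read from PDB files via Biopython; only polymer (protein)
residues and heavy atoms are kept, so waters, ions, HETATM ligands and
hydrogens never reach the contact calculation. Docked poses are read from
three dialects:

``swissdock``
    A SwissDock-style cluster PDB: each pose is a MODEL preceded by
    ``REMARK Cluster: <c> Element: <e>`` and ``REMARK FullFitness: <value>``
    lines. The cluster-level FullFitness is assigned to every member pose.
``multimodel_pdb``
    A plain multi-model PDB plus a two-column TSV sidecar
    (pose_id <tab> energy), one row per MODEL in file order.
``sdf``
    An SDF file whose named property holds the energy (RDKit-parsed).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .datatypes import LigandPose, ReceptorStructure, ResidueRecord
from .errors import EmptyStructureError, FormatError, PoseEnergyError

_HYDROGENS = {"H", "D"}


# ---------------------------------------------------------------------------
# receptor reading
# ---------------------------------------------------------------------------

def read_receptor(
    path: str | Path,
    model: Optional[int] = None,
    include_hydrogens: bool = False,
) -> ReceptorStructure:
    """Read a PDB receptor into a :class:`ReceptorStructure`.

    Keeps polymer protein residues only (no waters, ions or HETATM ligands),
    heavy atoms only unless ``include_hydrogens``. Alternate locations are
    resolved to the highest-occupancy conformer (ties: first encountered).
    ``model`` selects a MODEL by its serial number; default is the first.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        biostruct = parser.get_structure("receptor", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(biostruct.get_models())
    if not models:
        raise EmptyStructureError(f"no MODEL records in {path}")
    if model is None:
        chosen = models[0]
    else:
        by_serial = {m.serial_num: m for m in models}
        if model not in by_serial:
            raise FormatError(
                f"model {model} not found in {path}; available: {sorted(by_serial)}"
            )
        chosen = by_serial[model]

    residues: list[ResidueRecord] = []
    for chain in chosen:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " ":  # waters ('W') and HETATM ('H_...') excluded
                continue
            elements, coords = [], []
            for atom in res.get_unpacked_list():
                if atom.is_disordered() or atom.get_altloc() not in (" ", ""):
                    continue  # replaced below by the selected conformer
                _append_atom(atom, elements, coords, include_hydrogens)
            # disordered atoms: Bio.PDB's selected child is the
            # highest-occupancy conformer, ties keeping the first seen
            for atom in res:
                if atom.is_disordered():
                    _append_atom(atom.selected_child, elements, coords,
                                 include_hydrogens)
            if not elements:
                continue
            key = (chain.id, int(resseq), icode.strip())
            residues.append(ResidueRecord(key, res.get_resname().strip(),
                                          elements, np.array(coords)))
    if not residues:
        raise EmptyStructureError(f"no protein residues in {path}")
    return ReceptorStructure(residues, source_path=str(path),
                             model_index=chosen.serial_num)


def _append_atom(atom, elements: list, coords: list, include_hydrogens: bool) -> None:
    element = (atom.element or "").strip().upper()
    if not element:
        element = "".join(c for c in atom.get_name() if c.isalpha())[:1].upper()
    if not include_hydrogens and element in _HYDROGENS:
        return
    elements.append(element)
    coords.append(atom.get_coord().astype(float))


# ---------------------------------------------------------------------------
# pose reading
# ---------------------------------------------------------------------------

def read_poses(
    path: str | Path,
    dialect: str,
    energy_tag: Optional[str] = None,
    sidecar: Optional[str | Path] = None,
    representatives_only: bool = False,
    include_hydrogens: bool = False,
) -> list[LigandPose]:
    """Read docked ligand poses with per-pose energies.

    ``dialect`` is one of ``swissdock``, ``multimodel_pdb``, ``sdf``.
    For ``sdf``, ``energy_tag`` names the SDF property holding the energy;
    for ``multimodel_pdb``, ``sidecar`` points at the two-column energy TSV.
    ``representatives_only`` keeps only the first element of each SwissDock
    cluster.
    """
    path = Path(path)
    if dialect == "swissdock":
        poses = _read_swissdock(path, include_hydrogens)
        if representatives_only:
            seen: set[str] = set()
            kept = []
            for pose, cluster in poses:
                if cluster not in seen:
                    seen.add(cluster)
                    kept.append(pose)
            return kept
        return [p for p, _ in poses]
    if dialect == "multimodel_pdb":
        if sidecar is None:
            raise ValueError("multimodel_pdb dialect requires a sidecar energy table")
        return _read_multimodel(path, Path(sidecar), include_hydrogens)
    if dialect == "sdf":
        if energy_tag is None:
            raise ValueError("sdf dialect requires an energy_tag")
        return _read_sdf(path, energy_tag, include_hydrogens)
    raise ValueError(f"unknown pose dialect {dialect!r}")


def _parse_pdb_atom(line: str, include_hydrogens: bool):
    element = line[76:78].strip().upper()
    if not element:
        element = "".join(c for c in line[12:16] if c.isalpha())[:1].upper()
    if not include_hydrogens and element in _HYDROGENS:
        return None
    try:
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise FormatError(f"bad coordinate field in line: {line.rstrip()}") from exc
    return element, xyz


def _read_swissdock(path: Path, include_hydrogens: bool) -> list[tuple[LigandPose, str]]:
    poses: list[tuple[LigandPose, str]] = []
    cluster = element_no = None
    energy: Optional[float] = None
    elements: list[str] = []
    coords: list[tuple] = []
    in_model = False

    def flush() -> None:
        nonlocal elements, coords
        if not elements:
            return
        pid = f"c{cluster}.{element_no}"
        if energy is None:
            raise PoseEnergyError(f"pose {pid} in {path} has no FullFitness energy")
        poses.append(
            (LigandPose(pid, elements, np.array(coords), energy), str(cluster))
        )
        elements, coords = [], []

    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty pose file {path}")
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "REMARK":
            body = line[6:].strip()
            if body.lower().startswith("cluster:"):
                flush()  # files without ENDMDL delimiters: REMARK starts a pose
                parts = body.replace(":", " ").split()
                # "Cluster <c> Element <e>"
                try:
                    cluster = int(parts[1])
                    element_no = int(parts[3]) if len(parts) > 3 else 0
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"bad cluster line: {line.rstrip()}") from exc
                energy = None
            elif body.lower().startswith("fullfitness:"):
                try:
                    energy = float(body.split(":", 1)[1])
                except ValueError as exc:
                    raise PoseEnergyError(
                        f"unparseable FullFitness for cluster {cluster}: {line.rstrip()}"
                    ) from exc
        elif rec == "MODEL":
            in_model = True
        elif rec == "ENDMDL":
            flush()
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_pdb_atom(line, include_hydrogens)
            if parsed is not None:
                elements.append(parsed[0])
                coords.append(parsed[1])
    flush()
    if not poses:
        raise FormatError(f"no poses found in {path}")
    return poses


def _read_multimodel(path: Path, sidecar: Path, include_hydrogens: bool) -> list[LigandPose]:
    table: list[tuple[str, float]] = []
    for raw in sidecar.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise FormatError(f"bad sidecar row in {sidecar}: {raw!r}")
        try:
            table.append((fields[0], float(fields[1])))
        except ValueError as exc:
            raise PoseEnergyError(
                f"unparseable energy for pose {fields[0]} in {sidecar}"
            ) from exc

    models: list[tuple[list[str], list[tuple]]] = []
    elements: list[str] = []
    coords: list[tuple] = []
    saw_model = False
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty pose file {path}")
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            elements, coords = [], []
        elif rec == "ENDMDL":
            models.append((elements, coords))
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_pdb_atom(line, include_hydrogens)
            if parsed is not None:
                elements.append(parsed[0])
                coords.append(parsed[1])
    if not saw_model and elements:  # single-pose file without MODEL records
        models.append((elements, coords))
    if not models:
        raise FormatError(f"no poses found in {path}")
    if len(models) != len(table):
        raise PoseEnergyError(
            f"{path} has {len(models)} poses but sidecar {sidecar} has "
            f"{len(table)} energy rows"
        )
    return [
        LigandPose(pid, els, np.array(xyz), e)
        for (els, xyz), (pid, e) in zip(models, table)
    ]


def _read_sdf(path: Path, energy_tag: str, include_hydrogens: bool) -> list[LigandPose]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=not include_hydrogens,
                                  sanitize=False)
    poses: list[LigandPose] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"unreadable SDF record {i} in {path}")
        pid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") and mol.GetProp("_Name").strip() else f"sdf{i}"
        if not mol.HasProp(energy_tag):
            raise PoseEnergyError(f"pose {pid} lacks SDF property {energy_tag!r}")
        try:
            energy = float(mol.GetProp(energy_tag))
        except ValueError as exc:
            raise PoseEnergyError(f"unparseable energy for pose {pid}") from exc
        conf = mol.GetConformer()
        elements, coords = [], []
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol().upper()
            if not include_hydrogens and sym in _HYDROGENS:
                continue
            p = conf.GetAtomPosition(atom.GetIdx())
            elements.append(sym)
            coords.append((p.x, p.y, p.z))
        poses.append(LigandPose(pid, elements, np.array(coords), energy))
    if not poses:
        raise FormatError(f"no poses found in {path}")
    return poses


# ---------------------------------------------------------------------------
# writers (PDB fixed-width, 3-decimal coordinates)
# ---------------------------------------------------------------------------

def _atom_line(record: str, serial: int, name: str, resname: str, chain: str,
               resseq: int, icode: str, xyz, occ: float = 1.0,
               b: float = 0.0, element: str = "") -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record:<6s}{serial:>5d} {name_field:<4s} {resname:>3s} {chain:1s}"
        f"{resseq:>4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def receptor_to_pdb(structure: ReceptorStructure,
                    bfactors: Optional[dict] = None) -> str:
    """Render a receptor as PDB text, optionally writing per-residue values
    (e.g. conservation scores) into the B-factor column."""
    lines = []
    serial = 1
    for res in structure.residues:
        chain, resseq, icode = res.key
        b = 0.0 if bfactors is None else float(bfactors.get(res.key, 0.0))
        counts: dict[str, int] = {}
        for element, xyz in zip(res.elements, res.coords):
            counts[element] = counts.get(element, 0) + 1
            name = f"{element}{counts[element]}"
            lines.append(_atom_line("ATOM", serial, name, res.name, chain,
                                    resseq, icode, xyz, b=b, element=element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_receptor(structure: ReceptorStructure, path: str | Path,
                   bfactors: Optional[dict] = None) -> None:
    Path(path).write_text(receptor_to_pdb(structure, bfactors))


def pose_to_pdb_lines(pose: LigandPose, start_serial: int = 1) -> list[str]:
    lines = []
    counts: dict[str, int] = {}
    for i, (element, xyz) in enumerate(zip(pose.elements, pose.coords)):
        counts[element] = counts.get(element, 0) + 1
        name = f"{element}{counts[element]}"
        lines.append(_atom_line("HETATM", start_serial + i, name, "LIG", "X",
                                1, "", xyz, element=element))
    return lines


def write_pose(pose: LigandPose, path: str | Path) -> None:
    """Write a single pose as a small HETATM-only PDB file."""
    Path(path).write_text("\n".join(pose_to_pdb_lines(pose)) + "\nEND\n")


def write_poses_swissdock(poses: Sequence[LigandPose], path: str | Path) -> None:
    """Write poses as a SwissDock-style cluster file (one cluster per pose
    unless pose ids follow the ``c<cluster>.<element>`` convention)."""
    lines = []
    for i, pose in enumerate(poses):
        cluster, element_no = i, 0
        pid = pose.pose_id
        if pid.startswith("c") and "." in pid:
            try:
                cluster, element_no = (int(x) for x in pid[1:].split(".", 1))
            except ValueError:
                pass
        lines.append(f"REMARK Cluster: {cluster} Element: {element_no}")
        lines.append(f"REMARK FullFitness: {pose.energy_score:.4f}")
        lines.append(f"MODEL {i + 1:>8d}")
        lines.extend(pose_to_pdb_lines(pose))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_poses_multimodel(poses: Sequence[LigandPose], pdb_path: str | Path,
                           sidecar_path: str | Path) -> None:
    """Write poses as a multi-model PDB plus a (pose_id, energy) TSV sidecar."""
    lines = []
    rows = []
    for i, pose in enumerate(poses):
        lines.append(f"MODEL {i + 1:>8d}")
        lines.extend(pose_to_pdb_lines(pose))
        lines.append("ENDMDL")
        rows.append(f"{pose.pose_id}\t{pose.energy_score:.4f}")
    lines.append("END")
    Path(pdb_path).write_text("\n".join(lines) + "\n")
    Path(sidecar_path).write_text("\n".join(rows) + "\n")
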