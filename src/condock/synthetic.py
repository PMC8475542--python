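"""Seeded synthetic fixtures: toy receptors with a planted conserved pocket,
matching alignments/grades, and true-plus-decoy pose sets.

The pseudo-receptor is a poly-alanine cylindrical bundle enclosing a central
cavity, a cartoon of the seven-helix fold's extracellular ligand cavity:
residues sit on a cylinder lattice (8 columns around the axis, 3 A rise per
row, slight twist), each a rigid 5-heavy-atom unit whose CB points inward.
A pocket is planted near the cavity wall; pocket residues receive a high
conservation level and everything else a low background level, realised both
as 0-9 grades and as an alignment whose per-column retention probability
equals the planted level. The pose set holds one true pose centered in the
pocket and decoys scattered on the outer surface, with the true pose's
energy placed at a chosen percentile of the decoy energy distribution — at
high percentiles docking alone ranks a decoy first and only the
conservation-weighted score recovers the planted site.

Every artifact is a pure function of the :class:`ScenarioSpec` (seed
included); written files are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .conservation import AMINO_ACIDS, Alignment, GradesTable
from .datatypes import LigandPose, ReceptorStructure, ResidueKey, ResidueRecord
from .errors import ScenarioError
from .sitescore import DEFAULT_CONTACT_CUTOFF, binding_site_residues

# pseudo-receptor geometry (Å / radians); one place on purpose
BUNDLE_RADIUS = 8.5
N_COLUMNS = 8
RISE_PER_ROW = 3.0
TWIST_PER_ROW = 0.3
CB_INSET = 1.6          # CB sits this far inside the backbone ring
POCKET_DEPTH = 3.0      # pocket center sits this far inside the anchor CB
DECOY_OFFSET = 4.0      # decoy centers float this far outside the backbone

# rigid 8-heavy-atom toy ligand (cube corners, mixed elements); not a
# chemically valid molecule — contact and center-of-mass math need none
LIGAND_ELEMENTS = ["C", "C", "C", "C", "N", "O", "C", "C"]
LIGAND_TEMPLATE = 0.9 * np.array([
    [-1, -1, -1], [1, -1, -1], [-1, 1, -1], [1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [-1, 1, 1], [1, 1, 1],
], dtype=float)

DECOY_ENERGY_MEAN = -3400.0   # SwissDock-FullFitness-like scale
DECOY_ENERGY_SD = 100.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic benchmark scenario."""

    seed: int
    n_residues: int = 60
    pocket_fraction: float = 0.2
    pocket_conservation: float = 0.9
    background_conservation: float = 0.2
    n_decoys: int = 10
    true_energy_percentile: float = 0.7
    n_msa_sequences: int = 50
    decoy_energy_mean: float = DECOY_ENERGY_MEAN
    decoy_energy_sd: float = DECOY_ENERGY_SD

    def __post_init__(self) -> None:
        for name in ("pocket_fraction", "pocket_conservation",
                     "background_conservation", "true_energy_percentile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScenarioError(f"{name}={v} outside [0, 1]")
        if self.pocket_conservation <= self.background_conservation:
            raise ScenarioError(
                "pocket conservation must exceed the background level")
        if self.n_decoys < 1:
            raise ScenarioError("a rescue scenario needs at least one decoy")
        if self.n_msa_sequences < 2:
            raise ScenarioError("alignment needs at least 2 sequences")
        if self.decoy_energy_sd <= 0:
            raise ScenarioError("decoy energy sd must be positive")


@dataclass
class Scenario:
    """A fully generated fixture: receptor, poses, alignment, grades, truth."""

    spec: ScenarioSpec
    receptor: ReceptorStructure
    poses: list[LigandPose]
    reference_pose: LigandPose
    alignment: Alignment
    grades: dict[int, int]          # residue ordinal (1-based) -> 0-9 grade
    levels: dict[int, float]        # planted conservation level per ordinal
    truth: str                      # pose_id of the planted true pose
    pocket_keys: frozenset[ResidueKey]

    def grades_table(self) -> GradesTable:
        letters = {p: "A" for p in self.grades}
        return GradesTable(dict(self.grades), letters)

    def profile(self):
        """The planted conservation mapped onto the receptor via the
        grades-import path (grade / 9)."""
        from .conservation import profile_from_grades

        return profile_from_grades(self.grades_table(), self.receptor)


# ---------------------------------------------------------------------------
# receptor
# ---------------------------------------------------------------------------

def _residue_frame(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outward unit vector, tangent unit vector and backbone center of
    lattice residue ``i``."""
    col, row = i % N_COLUMNS, i // N_COLUMNS
    theta = 2.0 * math.pi * col / N_COLUMNS + TWIST_PER_ROW * row
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    t = np.array([-math.sin(theta), math.cos(theta), 0.0])
    center = BUNDLE_RADIUS * u + np.array([0.0, 0.0, RISE_PER_ROW * row])
    return u, t, center


_K = np.array([0.0, 0.0, 1.0])


def _residue_atoms(i: int) -> tuple[list[str], np.ndarray]:
    u, t, c = _residue_frame(i)
    coords = np.stack([
        c + 1.2 * t,              # N
        c,                        # CA
        c - 1.2 * t,              # C
        c - 1.2 * t + 1.2 * _K,   # O
        c - CB_INSET * u,         # CB (points into the cavity)
    ])
    return ["N", "C", "C", "O", "C"], coords


def make_receptor(spec: ScenarioSpec) -> ReceptorStructure:
    """Deterministic poly-alanine bundle receptor for ``spec``."""
    n = spec.n_residues
    if n < 24:
        raise ScenarioError(
            f"n_residues={n} too small to close a cavity (minimum 24)")
    residues = []
    for i in range(n):
        elements, coords = _residue_atoms(i)
        residues.append(ResidueRecord(("A", i + 1, ""), "ALA", elements,
                                      np.round(coords, 3)))
    return ReceptorStructure(residues, source_path="<synthetic>", model_index=1)


def pocket_center(spec: ScenarioSpec) -> np.ndarray:
    """The planted pocket's anchor point, just inside the cavity wall."""
    n_rows = (spec.n_residues + N_COLUMNS - 1) // N_COLUMNS
    anchor_row = max(1, int(0.6 * (n_rows - 1)))
    anchor = anchor_row * N_COLUMNS  # column 0 of that row
    if anchor >= spec.n_residues:
        anchor = spec.n_residues - N_COLUMNS
    u, _, c = _residue_frame(anchor)
    return c - (CB_INSET + POCKET_DEPTH) * u


def pocket_residues(spec: ScenarioSpec,
                    receptor: ReceptorStructure) -> list[int]:
    """Indices of the planted pocket: the k residues nearest the pocket
    center (k = round(pocket_fraction * n_residues), at least 1)."""
    center = pocket_center(spec)
    dists = [np.linalg.norm(r.coords - center, axis=1).min()
             for r in receptor.residues]
    k = max(1, round(spec.pocket_fraction * spec.n_residues))
    return sorted(np.argsort(dists)[:k].tolist())


# ---------------------------------------------------------------------------
# alignment and grades
# ---------------------------------------------------------------------------

def mutate_sequences(target: str, levels: np.ndarray, n_sequences: int,
                     rng: np.random.Generator) -> Alignment:
    """Alignment of ``n_sequences`` homolog-like sequences: per column j each
    non-target sequence retains the target letter with probability
    ``levels[j]``, otherwise mutates to one of the 19 other residues."""
    if len(target) != len(levels):
        raise ValueError("levels length must match target length")
    others = {a: [b for b in AMINO_ACIDS if b != a] for a in AMINO_ACIDS}
    seqs = [("target", target)]
    for s in range(1, n_sequences):
        chars = []
        for j, a in enumerate(target):
            if rng.random() < levels[j]:
                chars.append(a)
            else:
                chars.append(others[a][rng.integers(19)])
        seqs.append((f"seq{s:03d}", "".join(chars)))
    return Alignment(seqs, len(target))


def make_alignment_and_grades(
    spec: ScenarioSpec,
    receptor: ReceptorStructure,
    pocket: list[int],
    rng: np.random.Generator,
) -> tuple[Alignment, dict[int, int], dict[int, float]]:
    """Alignment plus planted grades for a scenario: pocket columns at the
    pocket conservation level, all others at the background level;
    grade = round(9 * level)."""
    n = spec.n_residues
    pocket_set = set(pocket)
    levels = np.array([
        spec.pocket_conservation if i in pocket_set
        else spec.background_conservation
        for i in range(n)
    ])
    alignment = mutate_sequences(receptor.sequence(), levels,
                                 spec.n_msa_sequences, rng)
    grades = {i + 1: int(round(9 * levels[i])) for i in range(n)}
    level_map = {i + 1: float(levels[i]) for i in range(n)}
    return alignment, grades, level_map


def make_recovery_alignment(
    seed: int, n_columns: int = 100, n_sequences: int = 50,
) -> tuple[np.ndarray, Alignment]:
    """A parameter-recovery fixture: random target sequence with per-column
    conservation levels drawn uniformly in [0, 1]. Returns (levels,
    alignment); the JSD profile should rank-correlate with the levels."""
    rng = np.random.default_rng(seed)
    target = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=n_columns))
    levels = rng.uniform(0.0, 1.0, size=n_columns)
    return levels, mutate_sequences(target, levels, n_sequences, rng)


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _place_ligand(center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.round(LIGAND_TEMPLATE @ _random_rotation(rng).T + center, 3)


def make_poses(
    spec: ScenarioSpec,
    receptor: ReceptorStructure,
    pocket: list[int],
    rng: np.random.Generator,
) -> tuple[list[LigandPose], LigandPose, str]:
    """True pose centered in the pocket plus surface decoys.

    Decoy energies are drawn from Normal(decoy_energy_mean,
    decoy_energy_sd); the true pose's energy is placed at
    ``true_energy_percentile`` of the realised decoy energies (0 -> best of
    all, 1 -> worst of all). Returns (poses in file order, reference pose,
    true pose id); the reference pose is the true pose itself.
    """
    pocket_keys = {receptor.residues[i].key for i in pocket}
    center = pocket_center(spec)

    true_coords = None
    for _ in range(20):
        coords = _place_ligand(center, rng)
        probe = LigandPose("probe", LIGAND_ELEMENTS, coords, -1.0)
        site = binding_site_residues(receptor, probe, DEFAULT_CONTACT_CUTOFF)
        if site.n >= 1 and site.residue_keys <= pocket_keys:
            true_coords = coords
            break
    if true_coords is None:
        raise ScenarioError("could not place the true pose inside the pocket")

    non_pocket = [i for i in range(spec.n_residues) if i not in set(pocket)]
    decoy_coords = []
    for _ in range(spec.n_decoys):
        placed = False
        for _try in range(60):
            i = non_pocket[rng.integers(len(non_pocket))]
            u, t, c = _residue_frame(i)
            jitter = rng.normal(0.0, 0.8, size=2)
            pos = c + DECOY_OFFSET * u + jitter[0] * t + jitter[1] * _K
            coords = _place_ligand(pos, rng)
            probe = LigandPose("probe", LIGAND_ELEMENTS, coords, -1.0)
            site = binding_site_residues(receptor, probe, DEFAULT_CONTACT_CUTOFF)
            if site.n == 0:
                continue
            overlap = len(site.residue_keys & pocket_keys) / site.n
            if overlap < 0.2:
                decoy_coords.append(coords)
                placed = True
                break
        if not placed:
            raise ScenarioError(
                "could not place a decoy off the pocket within retry budget")

    decoy_e = rng.normal(spec.decoy_energy_mean, spec.decoy_energy_sd,
                         size=spec.n_decoys)
    e_sorted = np.sort(decoy_e)
    m = spec.n_decoys
    k = int(math.floor(spec.true_energy_percentile * m))
    margin = spec.decoy_energy_sd / 10.0
    if k <= 0:
        true_energy = float(e_sorted[0] - margin)
    elif k >= m:
        true_energy = float(e_sorted[-1] + margin)
    else:
        true_energy = float(0.5 * (e_sorted[k - 1] + e_sorted[k]))

    true_at = int(rng.integers(spec.n_decoys + 1))
    poses: list[LigandPose] = []
    truth_id = ""
    d = 0
    for slot in range(spec.n_decoys + 1):
        pid = f"c{slot}.0"
        if slot == true_at:
            poses.append(LigandPose(pid, list(LIGAND_ELEMENTS), true_coords,
                                    round(true_energy, 4)))
            truth_id = pid
        else:
            poses.append(LigandPose(pid, list(LIGAND_ELEMENTS),
                                    decoy_coords[d],
                                    round(float(decoy_e[d]), 4)))
            d += 1
    reference = LigandPose("reference", list(LIGAND_ELEMENTS), true_coords,
                           round(true_energy, 4))
    return poses, reference, truth_id


# ---------------------------------------------------------------------------
# scenario assembly and I/O
# ---------------------------------------------------------------------------

def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Generate a complete scenario; pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    receptor = make_receptor(spec)
    pocket = pocket_residues(spec, receptor)
    alignment, grades, levels = make_alignment_and_grades(
        spec, receptor, pocket, rng)
    poses, reference, truth = make_poses(spec, receptor, pocket, rng)
    pocket_keys = frozenset(receptor.residues[i].key for i in pocket)

    # generation-time invariant checks
    true_pose = next(p for p in poses if p.pose_id == truth)
    site = binding_site_residues(receptor, true_pose, DEFAULT_CONTACT_CUTOFF)
    if not (site.n >= 1 and site.residue_keys <= pocket_keys):
        raise ScenarioError("true-pose site escaped the planted pocket")
    for pose in poses:
        if pose.pose_id == truth:
            continue
        dsite = binding_site_residues(receptor, pose, DEFAULT_CONTACT_CUTOFF)
        if dsite.n and len(dsite.residue_keys & pocket_keys) / dsite.n >= 0.2:
            raise ScenarioError(f"decoy {pose.pose_id} overlaps the pocket")

    return Scenario(spec, receptor, poses, reference, alignment, grades,
                    levels, truth, pocket_keys)


def write_scenario(scenario: Scenario, directory: str | Path) -> dict:
    """Write every artifact of a scenario; returns the file manifest.

    Emits the receptor, the pose set in both the SwissDock-style cluster
    dialect and the multimodel+sidecar dialect, the alignment, the grades
    table, the reference pose, truth.json and manifest.json. Byte-identical
    across runs for the same spec.
    """
    from .structure_io import (write_pose, write_poses_multimodel,
                               write_poses_swissdock, write_receptor)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "receptor": "receptor.pdb",
        "poses_swissdock": "poses_swissdock.pdb",
        "poses_multimodel": "poses_models.pdb",
        "pose_energies": "pose_energies.tsv",
        "alignment": "alignment.fasta",
        "grades": "grades.txt",
        "reference": "reference.pdb",
        "truth": "truth.json",
        "manifest": "manifest.json",
    }
    write_receptor(scenario.receptor, directory / files["receptor"])
    write_poses_swissdock(scenario.poses, directory / files["poses_swissdock"])
    write_poses_multimodel(scenario.poses,
                           directory / files["poses_multimodel"],
                           directory / files["pose_energies"])
    fasta = "".join(f">{sid}\n{seq}\n"
                    for sid, seq in scenario.alignment.sequences)
    (directory / files["alignment"]).write_text(fasta)
    grade_lines = ["# position residue grade"]
    grade_lines += [f"{p}\tA\t{g}" for p, g in sorted(scenario.grades.items())]
    (directory / files["grades"]).write_text("\n".join(grade_lines) + "\n")
    write_pose(scenario.reference_pose, directory / files["reference"])
    truth = {
        "truth": scenario.truth,
        "pocket_residues": [
            f"{c}:{r}{i}" for c, r, i in sorted(scenario.pocket_keys)
        ],
    }
    (directory / files["truth"]).write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n")
    manifest = {
        "spec": dataclasses.asdict(scenario.spec),
        "truth": scenario.truth,
        "files": files,
    }
    (directory / files["manifest"]).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def regenerate_from_manifest(path: str | Path) -> Scenario:
    """Rebuild the exact scenario recorded in a manifest.json."""
    manifest = json.loads(Path(path).read_text())
    return generate_scenario(ScenarioSpec(**manifest["spec"]))
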