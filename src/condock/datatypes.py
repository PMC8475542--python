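"""Core data model: receptor structures, docked poses, conservation profiles,
binding sites and ranked predictions.

Residues are identified throughout by a *residue key*: the tuple
``(chain_id, residue_number, insertion_code)``, with ``""`` for a blank
insertion code. Coordinates are Ångström everywhere; no unit conversion is
ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

ResidueKey = Tuple[str, int, str]


def format_residue_key(key: ResidueKey) -> str:
    """Render a residue key as e.g. ``A:42`` or ``A:42B`` (with icode)."""
    chain, resseq, icode = key
    return f"{chain}:{resseq}{icode}"


@dataclass
class ResidueRecord:
    """One polymer residue: identity plus its heavy atoms."""

    key: ResidueKey
    name: str                       # 3-letter residue code
    elements: list[str]             # one entry per atom, e.g. "C", "N"
    coords: np.ndarray              # (n_atoms, 3) float array, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if len(self.elements) == 0:
            raise ValueError("residue must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in residue {self.key}")


@dataclass
class ReceptorStructure:
    """A parsed protein model: ordered polymer residues with heavy atoms."""

    residues: list[ResidueRecord]
    source_path: str = ""
    model_index: int = 1

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in structure")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.elements) for r in self.residues)

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All atom coordinates plus, per atom, the index of its residue."""
        coords = np.concatenate([r.coords for r in self.residues])
        idx = np.concatenate(
            [np.full(len(r.elements), i) for i, r in enumerate(self.residues)]
        )
        return coords, idx

    def sequence(self) -> str:
        """One-letter amino-acid sequence in residue order ('X' if unknown)."""
        from Bio.PDB.Polypeptide import protein_letters_3to1

        return "".join(
            protein_letters_3to1.get(r.name.upper(), "X") for r in self.residues
        )


@dataclass
class LigandPose:
    """One docked ligand pose with its docking-program energy score.

    ``energy_score`` is the docking fitness value as reported (e.g. SwissDock
    FullFitness); more negative means more favorable.
    """

    pose_id: str
    elements: list[str]
    coords: np.ndarray
    energy_score: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) == 0:
            raise ValueError(f"pose {self.pose_id} has no atoms")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in pose {self.pose_id}")
        if not np.isfinite(self.energy_score):
            raise ValueError(f"non-finite energy for pose {self.pose_id}")

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "LigandPose":
        """Return a rigidly transformed copy (x -> R x + t)."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation, dtype=float)
        return LigandPose(self.pose_id, list(self.elements), new, self.energy_score)


@dataclass
class ConservationProfile:
    """Per-residue conservation values in [0, 1], keyed by residue key.

    ``provenance`` records whether the values were imported ConSurf-style
    grades (``"consurf_grades"``, value = grade / 9 exactly) or computed by
    the internal Jensen-Shannon divergence scorer (``"jsd"``).
    """

    values: dict[ResidueKey, float]
    provenance: str = "jsd"
    raw_grades: Optional[dict[ResidueKey, int]] = None

    def __post_init__(self) -> None:
        if self.provenance not in ("consurf_grades", "jsd"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        for key, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"conservation value {v} for {format_residue_key(key)} outside [0, 1]"
                )

    def __getitem__(self, key: ResidueKey) -> float:
        return self.values[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.values

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BindingSite:
    """The receptor residues in contact with one ligand pose."""

    residue_keys: frozenset[ResidueKey]
    conservation: dict[ResidueKey, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.residue_keys)

    def sorted_keys(self) -> list[ResidueKey]:
        return sorted(self.residue_keys)


@dataclass
class RankedPrediction:
    """Per-pose scoring record produced by :func:`condock.sitescore.rank_poses`.

    ``condock_score`` is the exact product conservation_score * energy_score;
    ranks are 1-based, ascending in condock score (most negative first).
    Poses that could not be scored carry ``rank=None`` and a ``reason``.
    """

    pose_id: str
    energy_score: float
    conservation_score: Optional[float]
    condock_score: Optional[float]
    rank: Optional[int]
    site: BindingSite
    pose: Optional[LigandPose] = None
    reason: Optional[str] = None


@dataclass
class SiteComparison:
    """Agreement between a predicted and a reference binding site."""

    com_distance: float
    predicted_site: BindingSite
    reference_site: BindingSite
    jaccard: Optional[float]
    shared_residues: frozenset[ResidueKey]
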