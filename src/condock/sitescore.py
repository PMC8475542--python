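"""The combined conservation x docking score.

For each docked pose, the binding site is the set of receptor residues with
at least one heavy atom within 3.5 A (inclusive) of any ligand heavy atom.
The Conservation Score is the arithmetic mean of the site residues'
conservation values; the combined score is the exact product

    condock = conservation_score * energy_score

so that with negative docking energies, a highly negative combined score
marks the most probable binding site. Poses are ranked ascending in the
combined score (most negative first), ties broken by ascending energy, then
pose id.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import (
    BindingSite,
    ConservationProfile,
    LigandPose,
    RankedPrediction,
    ReceptorStructure,
    format_residue_key,
)
from .errors import EmptySiteError, MissingConservationError

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 3.5  # Å, heavy-atom distance defining a contact


def binding_site_residues(
    structure: ReceptorStructure,
    pose: LigandPose,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    _tree: Optional[cKDTree] = None,
) -> BindingSite:
    """Residues with >= 1 heavy atom within ``cutoff`` (inclusive) of >= 1
    ligand heavy atom. An empty site is a valid result, not an error.

    ``_tree`` lets callers reuse a prebuilt KD-tree over the structure's
    atoms when scoring many poses.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords, res_idx = structure.atom_arrays()
    tree = _tree if _tree is not None else cKDTree(coords)
    hits = tree.query_ball_point(pose.coords, r=cutoff)
    residue_indices = {res_idx[i] for sub in hits for i in sub}
    keys = frozenset(structure.residues[i].key for i in residue_indices)
    return BindingSite(residue_keys=keys)


def attach_conservation(
    site: BindingSite,
    profile: ConservationProfile,
    missing: str = "skip",
) -> BindingSite:
    """Fill the site's per-residue conservation values from a profile.

    ``missing="skip"`` drops unmapped residues from the mean (logged);
    ``missing="error"`` raises instead.
    """
    values: dict = {}
    absent = []
    for key in site.residue_keys:
        if key in profile:
            values[key] = profile[key]
        else:
            absent.append(key)
    if absent:
        msg = ("no conservation value for site residue(s) "
               + ", ".join(format_residue_key(k) for k in sorted(absent)))
        if missing == "error":
            raise MissingConservationError(msg)
        logger.info("%s; excluded from the site mean", msg)
    return BindingSite(residue_keys=site.residue_keys, conservation=values)


def conservation_score(site: BindingSite) -> float:
    """Arithmetic mean of the site's per-residue conservation values."""
    if site.n == 0:
        raise EmptySiteError("cannot score an empty binding site")
    if not site.conservation:
        raise MissingConservationError(
            "site has no conservation values; call attach_conservation first"
        )
    return float(np.mean(list(site.conservation.values())))


def condock_score(conservation: float, energy: float) -> float:
    """Exact product of Conservation and Energy Scores (no clamping)."""
    if not np.isfinite(conservation) or not np.isfinite(energy):
        raise ValueError("conservation and energy must be finite")
    if not (0.0 <= conservation <= 1.0):
        raise ValueError(f"conservation {conservation} outside [0, 1]")
    if energy > 0:
        warnings.warn(
            "positive energy score: the product ordering assumes negative "
            "docking energies", stacklevel=2,
        )
    return conservation * energy


def rank_poses(
    structure: ReceptorStructure,
    poses: Sequence[LigandPose],
    profile: ConservationProfile,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    missing: str = "skip",
) -> list[RankedPrediction]:
    """Score and rank all poses by ascending combined score.

    Scoreable poses get ranks 1..k (ties: ascending energy, then pose id);
    poses with an empty site or no mappable conservation are appended
    unranked with a reason code. The rank-1 pose's site is the predicted
    binding site. Raises :class:`EmptySiteError` if no pose is scoreable.
    """
    coords, _ = structure.atom_arrays()
    tree = cKDTree(coords)
    scored: list[RankedPrediction] = []
    unranked: list[RankedPrediction] = []
    for pose in poses:
        site = binding_site_residues(structure, pose, cutoff, _tree=tree)
        if site.n == 0:
            unranked.append(RankedPrediction(
                pose.pose_id, pose.energy_score, None, None, None, site,
                pose=pose, reason="empty_site"))
            continue
        site = attach_conservation(site, profile, missing=missing)
        if not site.conservation:
            unranked.append(RankedPrediction(
                pose.pose_id, pose.energy_score, None, None, None, site,
                pose=pose, reason="no_conservation"))
            continue
        cons = conservation_score(site)
        scored.append(RankedPrediction(
            pose.pose_id, pose.energy_score, cons,
            condock_score(cons, pose.energy_score), None, site, pose=pose))
    if not scored:
        raise EmptySiteError("zero scoreable poses (all sites empty or unmapped)")
    scored.sort(key=lambda r: (r.condock_score, r.energy_score, r.pose_id))
    for i, rec in enumerate(scored, start=1):
        rec.rank = i
    if unranked:
        logger.info("%d pose(s) excluded from ranking", len(unranked))
    return scored + unranked


def ranked_to_tsv(ranked: Sequence[RankedPrediction],
                  header_lines: Sequence[str] = ()) -> str:
    """Render ranked predictions as TSV with an optional '#' header block."""
    lines = [f"# {h}" for h in header_lines]
    lines.append("pose_id\tenergy_score\tconservation_score\tcondock_score\t"
                 "rank\tn_site_residues\tsite_residues\treason")
    for rec in ranked:
        cons = "" if rec.conservation_score is None else f"{rec.conservation_score:.6f}"
        cds = "" if rec.condock_score is None else f"{rec.condock_score:.4f}"
        rank = "" if rec.rank is None else str(rec.rank)
        site = ";".join(format_residue_key(k) for k in rec.site.sorted_keys())
        lines.append(
            f"{rec.pose_id}\t{rec.energy_score:.4f}\t{cons}\t{cds}\t{rank}\t"
            f"{rec.site.n}\t{site}\t{rec.reason or ''}"
        )
    return "\n".join(lines) + "\n"
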