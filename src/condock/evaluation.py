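"""Benchmarking predictions against a reference ligand placement.

The headline metric is the Euclidean distance between the centers of mass
of the predicted and reference ligand coordinates. Unlike RMSD it needs no
atom matching, which suits site-level (rather than pose-level) evaluation.
Residue-set agreement between predicted and reference binding sites is
summarised by the Jaccard index.
"""

from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    BindingSite,
    ConservationProfile,
    LigandPose,
    RankedPrediction,
    ReceptorStructure,
    SiteComparison,
    format_residue_key,
)
from .sitescore import DEFAULT_CONTACT_CUTOFF, binding_site_residues

#: Standard atomic masses (u) for elements common in receptors and ligands.
ATOMIC_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
    "SE": 78.971, "BR": 79.904, "I": 126.904,
}

DEFAULT_SUCCESS_THRESHOLD = 4.0  # Å between predicted and reference COM


def center_of_mass(pose: LigandPose, weighting: str = "mass") -> np.ndarray:
    """Center of mass of a pose; ``weighting`` is ``mass`` (standard atomic
    masses) or ``geometric`` (unweighted centroid)."""
    if weighting == "geometric":
        return pose.coords.mean(axis=0)
    if weighting != "mass":
        raise ValueError(f"unknown weighting {weighting!r}")
    unknown = sorted({e for e in pose.elements if e.upper() not in ATOMIC_MASSES})
    if unknown:
        raise ValueError(f"no atomic mass for element(s): {', '.join(unknown)}")
    masses = np.array([ATOMIC_MASSES[e.upper()] for e in pose.elements])
    return (masses[:, None] * pose.coords).sum(axis=0) / masses.sum()


def com_distance(predicted: LigandPose, reference: LigandPose,
                 weighting: str = "mass") -> float:
    """Distance between the two poses' centers of mass; the poses need not
    share atom counts or ordering."""
    return float(np.linalg.norm(
        center_of_mass(predicted, weighting) - center_of_mass(reference, weighting)
    ))


def matched_rmsd(predicted: LigandPose, reference: LigandPose) -> Optional[float]:
    """Plain matched-atom RMSD in file order, as an optional diagnostic.
    Returns None when atom counts differ (no graph matching is attempted)."""
    if len(predicted.coords) != len(reference.coords):
        return None
    d = predicted.coords - reference.coords
    return float(math.sqrt((d * d).sum() / len(d)))


def compare_sites(predicted: BindingSite, reference: BindingSite
                  ) -> tuple[Optional[float], frozenset]:
    """Jaccard index and shared residues of two binding sites.

    Both sites empty -> the index is undefined and reported as None.
    """
    shared = predicted.residue_keys & reference.residue_keys
    union = predicted.residue_keys | reference.residue_keys
    if not union:
        return None, frozenset()
    return len(shared) / len(union), frozenset(shared)


def site_comparison(predicted_pose: LigandPose, reference_pose: LigandPose,
                    structure: ReceptorStructure,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    weighting: str = "mass") -> SiteComparison:
    """Full predicted-vs-reference comparison for a pair of poses. The
    reference site is derived from the reference pose with the same contact
    cutoff, keeping the two sites commensurable."""
    pred_site = binding_site_residues(structure, predicted_pose, cutoff)
    ref_site = binding_site_residues(structure, reference_pose, cutoff)
    jac, shared = compare_sites(pred_site, ref_site)
    return SiteComparison(
        com_distance=com_distance(predicted_pose, reference_pose, weighting),
        predicted_site=pred_site, reference_site=ref_site,
        jaccard=jac, shared_residues=shared,
    )


def evaluate_prediction(
    ranked: Sequence[RankedPrediction],
    reference_pose: LigandPose,
    structure: ReceptorStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    success_threshold: float = DEFAULT_SUCCESS_THRESHOLD,
    weighting: str = "mass",
) -> dict:
    """Per-pose benchmark report against a reference ligand placement.

    Each row carries the pose's rank, its COM distance to the reference,
    the Jaccard overlap with the reference's own contact site, and a
    success flag (COM distance <= ``success_threshold``). The summary
    repeats these for the rank-1 pose — the predicted binding site.
    """
    if not ranked:
        raise ValueError("no ranked predictions to evaluate")
    if success_threshold <= 0:
        raise ValueError("success threshold must be positive")
    ref_site = binding_site_residues(structure, reference_pose, cutoff)
    rows = []
    for rec in ranked:
        if rec.pose is None:
            raise ValueError(f"prediction {rec.pose_id} carries no pose coordinates")
        dist = com_distance(rec.pose, reference_pose, weighting)
        jac, shared = compare_sites(rec.site, ref_site)
        rows.append({
            "pose_id": rec.pose_id,
            "rank": rec.rank,
            "com_distance": dist,
            "jaccard": jac,
            "success": bool(dist <= success_threshold),
            "rmsd": matched_rmsd(rec.pose, reference_pose),
            "n_shared_residues": len(shared),
        })
    top = next((r for r in rows if r["rank"] == 1), None)
    if top is None:
        raise ValueError("no rank-1 pose among the predictions")
    return {
        "rows": rows,
        "summary": {
            "top_pose_id": top["pose_id"],
            "top_com_distance": top["com_distance"],
            "top_jaccard": top["jaccard"],
            "success": top["success"],
            "success_threshold": success_threshold,
            "weighting": weighting,
        },
    }


def report_to_tsv(report: dict, header_lines: Sequence[str] = ()) -> str:
    lines = [f"# {h}" for h in header_lines]
    lines.append("pose_id\trank\tcom_distance\tjaccard\tsuccess\trmsd")
    for row in report["rows"]:
        rank = "" if row["rank"] is None else str(row["rank"])
        jac = "" if row["jaccard"] is None else f"{row['jaccard']:.4f}"
        rmsd = "" if row["rmsd"] is None else f"{row['rmsd']:.3f}"
        lines.append(f"{row['pose_id']}\t{rank}\t{row['com_distance']:.3f}\t"
                     f"{jac}\t{str(row['success']).lower()}\t{rmsd}")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
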