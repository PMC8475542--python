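"""Per-residue conservation: imported ConSurf-style grades or an internal
Jensen-Shannon divergence (JSD) scorer over a multiple sequence alignment.

The JSD scorer follows the standard column-conservation formulation: the
column's amino-acid frequency distribution P (gaps excluded) is compared to
a background distribution B via

    JSD(P, B) = 1/2 KL(P || M) + 1/2 KL(B || M),   M = (P + B) / 2

with base-2 logarithms, so the score already lies in [0, 1] (1 bit is the
maximum). A pseudocount of 1/(20 * n_seq) is added to the column
frequencies (and the result renormalised) to avoid zero-support terms.
With the gap penalty on, the score is multiplied by the column's non-gap
fraction, down-weighting ragged columns.

ConSurf-style grades are integers 0-9 (9 = retained in all organisms);
they are normalised to [0, 1] by exact division by 9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import ConservationProfile, ReceptorStructure, format_residue_key
from .errors import FormatError, MappingError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Background amino-acid frequencies underlying the BLOSUM62 matrix
#: (Henikoff & Henikoff), normalised to sum to 1.
BLOSUM62_BACKGROUND = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)


@dataclass
class Alignment:
    """A multiple sequence alignment over the 20 residues, 'X' and '-'."""

    sequences: list[tuple[str, str]]  # (id, aligned sequence)
    ncol: int

    def ids(self) -> list[str]:
        return [sid for sid, _ in self.sequences]

    def get(self, seq_id: str) -> str:
        for sid, seq in self.sequences:
            if sid == seq_id:
                return seq
        raise KeyError(f"sequence {seq_id!r} not in alignment")

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.sequences]


def _clean_letter(c: str) -> str:
    c = c.upper()
    if c in _AA_INDEX or c == "-":
        return c
    if c in (".", "~"):
        return "-"
    return "X"


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal multiple sequence alignment.

    Requires >= 2 sequences of identical length; non-standard letters are
    mapped to 'X'.
    """
    from Bio import AlignIO

    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except Exception as exc:
        raise FormatError(f"cannot parse {format} alignment {path}: {exc}") from exc
    seqs = [(rec.id, "".join(_clean_letter(c) for c in str(rec.seq)))
            for rec in msa]
    if len(seqs) < 2:
        raise FormatError(
            f"alignment {path} has {len(seqs)} sequence(s); conservation "
            "needs at least 2"
        )
    ncol = len(seqs[0][1])
    if any(len(s) != ncol for _, s in seqs):
        raise FormatError(f"ragged alignment in {path}")
    return Alignment(seqs, ncol)


def _resolve_background(background) -> np.ndarray:
    if background is None or background == "uniform":
        return UNIFORM_BACKGROUND
    if isinstance(background, str):
        if background == "blosum62":
            return BLOSUM62_BACKGROUND
        raise ValueError(f"unknown background {background!r}")
    b = np.asarray(background, dtype=float)
    if b.shape != (20,) or not np.isclose(b.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")
    return b


def jsd_column_score(
    column: Sequence[str],
    background=None,
    gap_penalty: bool = True,
    pseudocount: Optional[float] = None,
) -> float:
    """Jensen-Shannon divergence conservation score of one column, in [0, 1].

    ``background`` is ``"uniform"`` (default), ``"blosum62"`` or 20
    frequencies. ``pseudocount`` defaults to 1/(20 * n_seq) where n_seq is
    the column height; it is added to the column's relative frequencies and
    renormalised. An all-gap column scores 0 with a warning.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    b = _resolve_background(background)
    letters = [_clean_letter(c) for c in column]
    counts = np.zeros(20)
    for c in letters:
        if c in _AA_INDEX:
            counts[_AA_INDEX[c]] += 1
    n_obs = counts.sum()
    if n_obs == 0:
        warnings.warn("all-gap (or all-unknown) column scored 0", stacklevel=2)
        return 0.0
    eps = 1.0 / (20 * len(column)) if pseudocount is None else pseudocount
    p = counts / n_obs
    p = (p + eps) / (1.0 + 20 * eps)
    m = 0.5 * (p + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log2(p / m), 0.0).sum()
        kl_bm = np.where(b > 0, b * np.log2(b / m), 0.0).sum()
    score = 0.5 * kl_pm + 0.5 * kl_bm
    score = float(min(max(score, 0.0), 1.0))
    if gap_penalty:
        nongap = sum(1 for c in letters if c != "-")
        score *= nongap / len(letters)
    return score


def profile_from_alignment(
    alignment: Alignment,
    target_id: str,
    background=None,
    gap_penalty: bool = True,
) -> dict[int, float]:
    """Per-position JSD conservation for one target sequence.

    Returns a mapping from the target's ungapped residue ordinal (1-based)
    to the column score; columns where the target has a gap are skipped.
    """
    target = alignment.get(target_id)
    scores: dict[int, float] = {}
    pos = 0
    for j in range(alignment.ncol):
        if target[j] == "-":
            continue
        pos += 1
        scores[pos] = jsd_column_score(
            alignment.column(j), background=background, gap_penalty=gap_penalty
        )
    return scores


def ungapped_sequence(alignment: Alignment, target_id: str) -> str:
    """The target's sequence with gaps removed."""
    return alignment.get(target_id).replace("-", "")


# ---------------------------------------------------------------------------
# ConSurf-style grades
# ---------------------------------------------------------------------------

@dataclass
class GradesTable:
    """Imported 0-9 conservation grades keyed by 1-based sequence position."""

    grades: dict[int, int]
    residues: dict[int, str]  # one-letter residue per position

    @property
    def positions(self) -> list[int]:
        return sorted(self.grades)

    @property
    def sequence(self) -> str:
        return "".join(self.residues[p] for p in self.positions)


def read_consurf_grades(path: str | Path) -> GradesTable:
    """Parse a whitespace-delimited grades table: position, one-letter
    residue, integer grade in [0, 9]. Lines starting with '#' are comments.
    """
    path = Path(path)
    grades: dict[int, int] = {}
    residues: dict[int, str] = {}
    rows = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected (position, residue, grade)")
        try:
            pos = int(fields[0])
            grade = int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable row {raw!r}") from exc
        if not (0 <= grade <= 9):
            raise FormatError(f"{path}:{lineno}: grade {grade} outside [0, 9]")
        if pos in grades:
            raise FormatError(f"{path}:{lineno}: duplicate position {pos}")
        grades[pos] = grade
        residues[pos] = _clean_letter(fields[1])
        rows += 1
    if rows == 0:
        raise FormatError(f"no grade rows in {path}")
    return GradesTable(grades, residues)


# ---------------------------------------------------------------------------
# mapping scores onto a structure
# ---------------------------------------------------------------------------

def map_profile_to_structure(
    scores: Mapping[int, float],
    sequence: str,
    structure: ReceptorStructure,
    provenance: str = "jsd",
    normalize: bool = True,
    raw_grades: Optional[Mapping[int, int]] = None,
    identity_threshold: float = 0.8,
) -> ConservationProfile:
    """Map per-position scores onto structure residues by global alignment.

    ``sequence`` is the one-letter sequence the 1-based positions of
    ``scores`` refer to. The structure's sequence is globally aligned to it
    (BLOSUM62, gap open/extend 10/0.5); aligned-position identity must reach
    ``identity_threshold`` or a :class:`MappingError` is raised. A residue
    letter mismatch at an aligned position triggers a warning but the score
    is still assigned. Structure residues with no aligned score carry no
    profile entry. For ``consurf_grades`` provenance with ``normalize`` on,
    values are grades divided by 9 exactly.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not sequence:
        raise MappingError("empty score sequence")
    struct_seq = structure.sequence()
    aligner = Align.PairwiseAligner(mode="global", open_gap_score=-10.0,
                                    extend_gap_score=-0.5)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln = aligner.align(struct_seq, sequence)[0]

    pairs: list[tuple[int, int]] = []  # (structure index, sequence index), 0-based
    for (s_start, s_end), (t_start, t_end) in zip(*aln.aligned):
        pairs.extend((s_start + k, t_start + k) for k in range(s_end - s_start))
    if not pairs:
        raise MappingError("no aligned positions between scores and structure")
    matches = sum(1 for si, ti in pairs if struct_seq[si] == sequence[ti])
    identity = matches / len(pairs)
    if identity < identity_threshold:
        raise MappingError(
            f"sequence-structure identity {identity:.2f} below threshold "
            f"{identity_threshold:.2f}; alignment:\n{aln}"
        )

    values: dict = {}
    kept_grades: dict = {}
    for si, ti in pairs:
        pos = ti + 1
        if pos not in scores:
            continue
        if struct_seq[si] != sequence[ti]:
            warnings.warn(
                f"residue letter mismatch at structure residue "
                f"{format_residue_key(structure.residues[si].key)} "
                f"({struct_seq[si]} vs {sequence[ti]}); score assigned anyway",
                stacklevel=2,
            )
        key = structure.residues[si].key
        v = float(scores[pos])
        if provenance == "consurf_grades" and normalize:
            v = v / 9.0
        values[key] = v
        if raw_grades is not None and pos in raw_grades:
            kept_grades[key] = int(raw_grades[pos])
    return ConservationProfile(
        values, provenance=provenance,
        raw_grades=kept_grades if raw_grades is not None else None,
    )


def profile_from_msa(
    alignment: Alignment,
    target_id: str,
    structure: ReceptorStructure,
    background=None,
    gap_penalty: bool = True,
    identity_threshold: float = 0.8,
) -> ConservationProfile:
    """Convenience: JSD column scores for ``target_id`` mapped onto the
    structure."""
    scores = profile_from_alignment(alignment, target_id,
                                    background=background,
                                    gap_penalty=gap_penalty)
    return map_profile_to_structure(
        scores, ungapped_sequence(alignment, target_id), structure,
        provenance="jsd", identity_threshold=identity_threshold,
    )


def profile_from_grades(
    table: GradesTable,
    structure: ReceptorStructure,
    normalize: bool = True,
    identity_threshold: float = 0.8,
) -> ConservationProfile:
    """Convenience: imported grades mapped onto the structure (grade/9)."""
    positions = table.positions
    # re-index onto a dense 1..L sequence for alignment
    scores = {i + 1: float(table.grades[p]) for i, p in enumerate(positions)}
    grades = {i + 1: table.grades[p] for i, p in enumerate(positions)}
    return map_profile_to_structure(
        scores, table.sequence, structure, provenance="consurf_grades",
        normalize=normalize, raw_grades=grades,
        identity_threshold=identity_threshold,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def profile_to_tsv(profile: ConservationProfile,
                   structure: ReceptorStructure) -> str:
    """Render a profile as TSV: chain, resseq, icode, resname, score."""
    lines = ["chain\tresseq\ticode\tresname\tscore"]
    for res in structure.residues:
        if res.key not in profile:
            continue
        chain, resseq, icode = res.key
        lines.append(f"{chain}\t{resseq}\t{icode}\t{res.name}\t"
                     f"{profile[res.key]:.6f}")
    return "\n".join(lines) + "\n"


def write_profile_tsv(profile: ConservationProfile,
                      structure: ReceptorStructure, path: str | Path) -> None:
    Path(path).write_text(profile_to_tsv(profile, structure))


def write_profile_bfactor_pdb(profile: ConservationProfile,
                              structure: ReceptorStructure,
                              path: str | Path) -> None:
    """Write the structure with conservation in the B-factor column, for
    coloring in a molecular viewer."""
    from .structure_io import write_receptor

    write_receptor(structure, path, bfactors=dict(profile.values))
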