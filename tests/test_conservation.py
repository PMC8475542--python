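"""Conservation scoring: JSD columns, grades import, structure mapping."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condock.conservation import (
    AMINO_ACIDS,
    Alignment,
    jsd_column_score,
    map_profile_to_structure,
    profile_from_alignment,
    profile_from_grades,
    read_alignment,
    read_consurf_grades,
)
from condock.errors import FormatError, MappingError
from helpers import make_structure


# ---------------------------------------------------------------------------
# alignment reading
# ---------------------------------------------------------------------------

def _write_fasta(path, seqs):
    path.write_text("".join(f">{i}\n{s}\n" for i, s in seqs))


@pytest.fixture()
def six_seq_alignment(tmp_path, rng):
    seqs = []
    for i in range(6):
        s = "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=40))
        seqs.append((f"s{i}", s))
    p = tmp_path / "aln.fasta"
    _write_fasta(p, seqs)
    return p, seqs


def test_read_fasta_alignment(six_seq_alignment):
    path, seqs = six_seq_alignment
    aln = read_alignment(path, "fasta")
    assert aln.ncol == 40
    assert aln.ids() == [i for i, _ in seqs]


def test_clustal_equals_fasta(six_seq_alignment, tmp_path):
    from Bio import AlignIO

    path, _ = six_seq_alignment
    aln_bio = AlignIO.read(str(path), "fasta")
    clustal = tmp_path / "aln.aln"
    AlignIO.write(aln_bio, str(clustal), "clustal")
    assert read_alignment(clustal, "clustal") == read_alignment(path, "fasta")


def test_single_sequence_errors(tmp_path):
    p = tmp_path / "one.fasta"
    _write_fasta(p, [("only", "ACDEF")])
    with pytest.raises(FormatError):
        read_alignment(p)


def test_ragged_alignment_errors(tmp_path):
    p = tmp_path / "ragged.fasta"
    _write_fasta(p, [("a", "ACDEF"), ("b", "ACD")])
    with pytest.raises(FormatError):
        read_alignment(p)


def test_nonstandard_letters_become_x(tmp_path):
    p = tmp_path / "odd.fasta"
    _write_fasta(p, [("a", "ACZEF"), ("b", "ACUEF")])
    aln = read_alignment(p)
    assert aln.get("a")[2] == "X" and aln.get("b")[2] == "X"


# ---------------------------------------------------------------------------
# JSD column score
# ---------------------------------------------------------------------------

def _jsd_oracle(column, n_total):
    """Independent direct evaluation of the normalised JSD formula for a
    gap-free column against the uniform background."""
    counts = {a: 0 for a in AMINO_ACIDS}
    for c in column:
        counts[c] += 1
    eps = 1.0 / (20 * n_total)
    n = sum(counts.values())
    p = np.array([(counts[a] / n + eps) / (1 + 20 * eps) for a in AMINO_ACIDS])
    b = np.full(20, 1 / 20)
    m = (p + b) / 2
    kl = lambda x, y: sum(xi * math.log2(xi / yi) for xi, yi in zip(x, y) if xi > 0)
    return 0.5 * kl(p, m) + 0.5 * kl(b, m)


def test_column_identical_to_background_scores_zero():
    assert jsd_column_score(list(AMINO_ACIDS), "uniform",
                            gap_penalty=False) == pytest.approx(0.0, abs=1e-12)


def test_fully_conserved_column_matches_hand_evaluated_jsd():
    expected = _jsd_oracle("AAAAAA", 6)
    assert jsd_column_score("AAAAAA", "uniform",
                            gap_penalty=False) == pytest.approx(expected, abs=1e-12)
    assert 0.0 < expected <= 1.0


def test_gap_penalty_is_exactly_the_nongap_fraction():
    full = jsd_column_score("AAAAAA", gap_penalty=True)
    half = jsd_column_score("AAA---", gap_penalty=True)
    assert half == full / 2


def test_all_gap_column_scores_zero_with_warning():
    with pytest.warns(UserWarning):
        assert jsd_column_score("------") == 0.0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.sampled_from(AMINO_ACIDS + "-"), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_jsd_permutation_invariant_and_bounded(column, rand):
    score = jsd_column_score(column)
    assert 0.0 <= score <= 1.0
    shuffled = list(column)
    rand.shuffle(shuffled)
    assert jsd_column_score(shuffled) == pytest.approx(score, abs=1e-12)


def test_whole_alignment_duplication_keeps_scores(rng):
    """Duplicating every sequence changes counts proportionally, so with a
    fixed pseudocount the frequency-based score is exactly unchanged. (The
    default pseudocount scales with column height, so there it only
    converges to invariance as the alignment deepens.)"""
    col = [AMINO_ACIDS[i] for i in rng.integers(20, size=10)]
    for bg in ("uniform", "blosum62"):
        a = jsd_column_score(col, bg, pseudocount=1e-3)
        b = jsd_column_score(col * 2, bg, pseudocount=1e-3)
        assert a == pytest.approx(b, abs=1e-12)
    # default pseudocount: deviation shrinks with depth
    d10 = abs(jsd_column_score(col * 2, "uniform")
              - jsd_column_score(col, "uniform"))
    d40 = abs(jsd_column_score(col * 8, "uniform")
              - jsd_column_score(col * 4, "uniform"))
    assert d40 < d10


# ---------------------------------------------------------------------------
# profile from alignment
# ---------------------------------------------------------------------------

def test_uniformly_conserved_alignment_gives_uniform_profile():
    seqs = [(f"s{i}", "MKVL") for i in range(5)]
    aln = Alignment(seqs, 4)
    scores = profile_from_alignment(aln, "s0")
    assert set(scores) == {1, 2, 3, 4}
    first = scores[1]
    assert all(v == pytest.approx(first, abs=1e-12) for v in scores.values())


def test_target_gap_columns_are_skipped():
    aln = Alignment([("t", "AC-EF"), ("o", "ACDEF"), ("p", "ACDEF")], 5)
    scores = profile_from_alignment(aln, "t")
    assert set(scores) == {1, 2, 3, 4}  # 4 ungapped target positions


def test_unknown_target_errors():
    aln = Alignment([("a", "AC"), ("b", "AC")], 2)
    with pytest.raises(KeyError):
        profile_from_alignment(aln, "nope")


def test_planted_levels_recovered_by_rank(rng):
    from scipy.stats import spearmanr

    from condock.synthetic import make_recovery_alignment

    levels, aln = make_recovery_alignment(seed=5, n_columns=80, n_sequences=50)
    scores = profile_from_alignment(aln, "target")
    rho = spearmanr(levels, [scores[i + 1] for i in range(len(levels))]).statistic
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# grades import
# ---------------------------------------------------------------------------

def test_read_grades_table(tmp_path):
    p = tmp_path / "grades.txt"
    p.write_text("# pos res grade\n1 M 9\n2 K 9\n3 V 3\n4 L 0\n5 A 7\n")
    table = read_consurf_grades(p)
    assert table.grades == {1: 9, 2: 9, 3: 3, 4: 0, 5: 7}
    assert table.sequence == "MKVLA"


@pytest.mark.parametrize("body", ["1 M 11\n", "1 M 9\n1 K 3\n", ""])
def test_bad_grades_tables_error(tmp_path, body):
    p = tmp_path / "grades.txt"
    p.write_text(body)
    with pytest.raises(FormatError):
        read_consurf_grades(p)


# ---------------------------------------------------------------------------
# mapping onto a structure
# ---------------------------------------------------------------------------

def test_identity_mapping_is_one_to_one():
    seq = "MKVLAWGREQ"
    structure = make_structure(seq)
    scores = {i + 1: 0.1 * i for i in range(len(seq))}
    prof = map_profile_to_structure(scores, seq, structure, provenance="jsd")
    assert len(prof) == len(seq)
    for i, key in enumerate(structure.residue_keys()):
        assert prof[key] == pytest.approx(0.1 * i)


def test_grade_nine_everywhere_normalises_to_one(tmp_path):
    seq = "MKVLAW"
    p = tmp_path / "grades.txt"
    p.write_text("".join(f"{i + 1} {c} 9\n" for i, c in enumerate(seq)))
    prof = profile_from_grades(read_consurf_grades(p), make_structure(seq))
    assert all(v == 1.0 for v in prof.values.values())


def test_grade_normalisation_roundtrip_is_exact(tmp_path):
    """value * 9 recovers the integer grade bit-for-bit, every grade 0-9."""
    seq = "MKVLAWGREQ"
    p = tmp_path / "grades.txt"
    p.write_text("".join(f"{i + 1} {c} {i}\n" for i, c in enumerate(seq)))
    prof = profile_from_grades(read_consurf_grades(p), make_structure(seq))
    assert prof.provenance == "consurf_grades"
    for key, v in prof.values.items():
        assert v * 9 == prof.raw_grades[key]


def test_extra_nterminal_structure_residues_are_unmapped(tmp_path):
    core = "MKVLAWGREQIDNE"
    structure = make_structure("GG" + core)  # 2 extra N-terminal residues
    p = tmp_path / "grades.txt"
    p.write_text("".join(f"{i + 1} {c} 5\n" for i, c in enumerate(core)))
    prof = profile_from_grades(read_consurf_grades(p), structure)
    keys = structure.residue_keys()
    assert keys[0] not in prof and keys[1] not in prof
    assert all(k in prof for k in keys[2:])


def test_low_identity_mapping_errors():
    structure = make_structure("MKVLAWGREQ")
    seq = "PPPPPPPPPP"
    scores = {i + 1: 0.5 for i in range(10)}
    with pytest.raises(MappingError):
        map_profile_to_structure(scores, seq, structure)


def test_letter_mismatch_warns_but_assigns():
    structure = make_structure("MKVLAWGREQ")
    seq = "MKVLAWGREL"  # one mismatch at the C-terminus
    scores = {i + 1: 0.5 for i in range(10)}
    with pytest.warns(UserWarning, match="mismatch"):
        prof = map_profile_to_structure(scores, seq, structure)
    assert len(prof) == 10


def test_profile_values_always_in_unit_interval(scenario):
    prof = scenario.profile()
    assert all(0.0 <= v <= 1.0 for v in prof.values.values())
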