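"""Contact detection, conservation averaging and the combined score."""

import numpy as np
import pytest

from condock.datatypes import (BindingSite, ConservationProfile, LigandPose,
                               ReceptorStructure, ResidueRecord)
from condock.errors import EmptySiteError, MissingConservationError
from condock.sitescore import (attach_conservation, binding_site_residues,
                               condock_score, conservation_score, rank_poses)
from helpers import brute_force_site, random_structure


def _spread_structure(positions):
    """One single-atom (CB-like) residue per position."""
    return ReceptorStructure([
        ResidueRecord(("A", i + 1, ""), "ALA", ["C"], np.array([p]))
        for i, p in enumerate(positions)
    ])


def _pose(coords, energy=-1.0, pid="p"):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return LigandPose(pid, ["C"] * len(coords), coords, energy)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def test_contact_at_3p4_angstrom_is_in_site():
    structure = _spread_structure([[0, 0, 0], [20, 0, 0], [40, 0, 0]])
    site = binding_site_residues(structure, _pose([[3.4, 0, 0]]), cutoff=3.5)
    assert site.residue_keys == {("A", 1, "")}


def test_contact_at_3p6_angstrom_is_excluded():
    structure = _spread_structure([[0, 0, 0], [20, 0, 0]])
    site = binding_site_residues(structure, _pose([[3.6, 0, 0]]), cutoff=3.5)
    assert site.n == 0


def test_cutoff_is_inclusive():
    structure = _spread_structure([[0, 0, 0]])
    site = binding_site_residues(structure, _pose([[3.5, 0, 0]]), cutoff=3.5)
    assert site.n == 1


def test_matches_brute_force_oracle_on_random_fixtures(rng):
    for _ in range(10):
        structure = random_structure(rng, n_residues=50)
        pose = _pose(rng.uniform(0, 30, size=(20, 3)))
        site = binding_site_residues(structure, pose, cutoff=3.5)
        assert site.residue_keys == brute_force_site(structure, pose, 3.5)


def test_site_invariant_under_joint_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    structure = random_structure(rng, n_residues=30)
    pose = _pose(rng.uniform(0, 30, size=(8, 3)))
    before = binding_site_residues(structure, pose, 3.5).residue_keys

    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    moved = ReceptorStructure([
        ResidueRecord(r.key, r.name, r.elements, r.coords @ R.T + t)
        for r in structure.residues
    ])
    after = binding_site_residues(moved, pose.transformed(R, t), 3.5)
    assert after.residue_keys == before


# ---------------------------------------------------------------------------
# conservation score and combined score
# ---------------------------------------------------------------------------

def test_conservation_score_is_the_arithmetic_mean():
    site = BindingSite(frozenset({("A", i, "") for i in (1, 2, 3)}),
                       {("A", 1, ""): 0.8, ("A", 2, ""): 0.6, ("A", 3, ""): 1.0})
    assert conservation_score(site) == pytest.approx(0.8)
    single = BindingSite(frozenset({("A", 9, "")}), {("A", 9, ""): 0.42})
    assert conservation_score(single) == pytest.approx(0.42)


def test_conservation_score_matches_mean_oracle(rng):
    vals = rng.uniform(0, 1, size=7)
    site = BindingSite(frozenset({("A", i, "") for i in range(7)}),
                       {("A", i, ""): v for i, v in enumerate(vals)})
    assert conservation_score(site) == pytest.approx(sum(vals) / 7, abs=1e-12)


def test_empty_site_cannot_be_scored():
    with pytest.raises(EmptySiteError):
        conservation_score(BindingSite(frozenset()))


def test_missing_conservation_policy():
    site = BindingSite(frozenset({("A", 1, ""), ("A", 2, "")}))
    profile = ConservationProfile({("A", 1, ""): 0.5})
    relaxed = attach_conservation(site, profile, missing="skip")
    assert conservation_score(relaxed) == pytest.approx(0.5)
    with pytest.raises(MissingConservationError):
        attach_conservation(site, profile, missing="error")


@pytest.mark.parametrize("cons,energy,expected", [
    (0.5, -100.0, -50.0),
    (0.0, -12345.0, 0.0),
    (1.0, -3421.7, -3421.7),
])
def test_condock_score_is_the_exact_product(cons, energy, expected):
    assert condock_score(cons, energy) == expected


def test_positive_energy_warns():
    with pytest.warns(UserWarning, match="positive energy"):
        assert condock_score(0.5, 10.0) == 5.0


def test_non_finite_inputs_error():
    with pytest.raises(ValueError):
        condock_score(0.5, float("nan"))
    with pytest.raises(ValueError):
        condock_score(1.5, -1.0)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _ranking_fixture():
    """Three far-apart single-residue 'pockets' with chosen conservation,
    and one single-atom pose touching each."""
    structure = _spread_structure([[0, 0, 0], [50, 0, 0], [100, 0, 0]])
    profile = ConservationProfile({("A", 1, ""): 0.9, ("A", 2, ""): 0.5,
                                   ("A", 3, ""): 0.9})
    poses = [_pose([[1.0, 0, 0]], energy=-100.0, pid="a"),
             _pose([[51.0, 0, 0]], energy=-150.0, pid="b"),
             _pose([[101.0, 0, 0]], energy=-50.0, pid="c")]
    return structure, poses, profile


def test_rank_poses_by_ascending_condock_score():
    structure, poses, profile = _ranking_fixture()
    ranked = rank_poses(structure, poses, profile)
    assert [(r.pose_id, r.rank) for r in ranked] == [("a", 1), ("b", 2), ("c", 3)]
    assert [r.condock_score for r in ranked] == pytest.approx([-90, -75, -45])


def test_exact_ties_break_by_energy():
    structure = _spread_structure([[0, 0, 0], [50, 0, 0]])
    profile = ConservationProfile({("A", 1, ""): 0.8, ("A", 2, ""): 1.0})
    poses = [_pose([[1.0, 0, 0]], energy=-100.0, pid="x"),   # 0.8 * -100 = -80
             _pose([[51.0, 0, 0]], energy=-80.0, pid="y")]   # 1.0 * -80  = -80
    ranked = rank_poses(structure, poses, profile)
    assert ranked[0].condock_score == ranked[1].condock_score == -80.0
    assert ranked[0].pose_id == "x"  # more negative energy wins the tie


def test_empty_site_poses_are_appended_unranked():
    structure, poses, profile = _ranking_fixture()
    poses.append(_pose([[500.0, 0, 0]], energy=-999.0, pid="far"))
    ranked = rank_poses(structure, poses, profile)
    assert [r.rank for r in ranked] == [1, 2, 3, None]
    assert ranked[-1].reason == "empty_site"


def test_zero_scoreable_poses_errors():
    structure, _, profile = _ranking_fixture()
    with pytest.raises(EmptySiteError):
        rank_poses(structure, [_pose([[500.0, 0, 0]], pid="far")], profile)


def test_ranking_is_a_gapless_permutation(scenario):
    ranked = rank_poses(scenario.receptor, scenario.poses, scenario.profile())
    assert len(ranked) == len(scenario.poses)
    ranks = [r.rank for r in ranked if r.rank is not None]
    assert ranks == list(range(1, len(ranks) + 1))


def test_constant_profile_reduces_to_energy_ranking(scenario):
    flat = ConservationProfile(
        {k: 0.5 for k in scenario.receptor.residue_keys()})
    ranked = rank_poses(scenario.receptor, scenario.poses, flat)
    by_energy = sorted((r for r in ranked if r.rank is not None),
                       key=lambda r: (r.energy_score, r.pose_id))
    assert [r.pose_id for r in ranked if r.rank is not None] == \
        [r.pose_id for r in by_energy]


def test_condock_monotone_in_conservation_and_energy(rng):
    for _ in range(50):
        c = rng.uniform(0.05, 0.95)
        e = -rng.uniform(10, 5000)
        dc = rng.uniform(0.01, 1 - c)
        de = rng.uniform(1, 100)
        assert condock_score(c + dc, e) < condock_score(c, e)
        assert condock_score(c, e - de) < condock_score(c, e)
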