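"""Structure / pose / profile I-O and scene assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from markermol.errors import FormatError, ValidationError
from markermol.structio import (AnchoredMolecule, Pose, SAXSProfile, Structure,
                                apply_pose, assemble_scene, interpolate_pose,
                                read_contact_table, read_pdb,
                                read_pose_trajectory, read_saxs_profile,
                                write_pdb, write_pose_trajectory,
                                write_saxs_profile)
from markermol.fixtures import hexaglycine_linker, lysine_sidechain

from conftest import random_rotation


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

TWO_ATOM_PDB = """\
ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  C2  LIG A   1       1.500   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BSER A   1       9.000   0.000   0.000  0.70  0.00           C
END
"""


def test_read_pdb_two_atoms(tmp_path):
    path = tmp_path / "two.pdb"
    path.write_text(TWO_ATOM_PDB)
    st_ = read_pdb(path)
    assert len(st_) == 2
    assert np.linalg.norm(st_.coords[1] - st_.coords[0]) == pytest.approx(1.5)
    assert [a.name for a in st_.atoms] == ["C1", "C2"]


@pytest.mark.parametrize("policy, expected_x", [
    ("first", 0.0),          # keeps conformer A (file order)
    ("occupancy", 9.0),      # keeps conformer B (occupancy 0.7)
])
def test_read_pdb_altloc_policies(tmp_path, policy, expected_x):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    st_ = read_pdb(path, altloc=policy)
    assert len(st_) == 1
    assert st_.coords[0][0] == pytest.approx(expected_x)


def test_read_pdb_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_pdb(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(FormatError):
        read_pdb(empty)
    bad = tmp_path / "bad.pdb"
    bad.write_text("ATOM      1  CA  GLY A   1       xx.000   0.000   0.000"
                   "  1.00  0.00           C\n")
    with pytest.raises(FormatError, match="line 1"):
        read_pdb(bad)


def test_hexaglycine_roundtrip(tmp_path):
    """Fixture -> PDB -> read back: 6 residues indexed 1..6, coordinates kept."""
    gly = hexaglycine_linker()
    path = tmp_path / "hexagly.pdb"
    write_pdb(gly, path)
    back = read_pdb(path)
    assert len(back) == 6
    assert [a.residue_index for a in back.atoms] == [1, 2, 3, 4, 5, 6]
    assert np.abs(back.coords - gly.coords).max() < 1e-3  # PDB prints 3 decimals


def test_conect_bonds_roundtrip(tmp_path):
    lys = lysine_sidechain()
    path = tmp_path / "lys.pdb"
    write_pdb(lys, path)
    back = read_pdb(path)
    assert back.bonds == lys.bonds


def test_structure_rejects_bad_bonds():
    atoms = hexaglycine_linker(2).atoms
    with pytest.raises(ValidationError):
        Structure(atoms, bonds=[(0, 0)])
    with pytest.raises(ValidationError):
        Structure(atoms, bonds=[(0, 5)])


# ---------------------------------------------------------------------------
# Poses
# ---------------------------------------------------------------------------

def test_pose_validation():
    with pytest.raises(ValidationError):
        Pose(quaternion=np.array([1.0, 1.0, 0.0, 0.0]))  # non-unit
    with pytest.raises(ValidationError):
        Pose(scale=0.0)
    assert Pose.identity().matrix == pytest.approx(np.eye(3))


def test_apply_pose_identity_and_translation(rng):
    pts = rng.normal(size=(5, 3))
    out = apply_pose(pts, Pose.identity(), anchor=np.zeros(3))
    assert out == pytest.approx(pts)
    shifted = apply_pose(pts, Pose(translation=np.array([10.0, 0, 0])),
                         anchor=np.zeros(3))
    assert shifted - pts == pytest.approx(np.tile([10.0, 0, 0], (5, 1)))


@settings(derandomize=True, deadline=None, max_examples=25)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 12))
def test_apply_pose_isometry(seed, n):
    """At scale 1 a pose is a rigid motion: pairwise distances survive."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=5.0, size=(n, 3))
    pose = Pose.from_rotation(random_rotation(rng), rng.normal(size=3))
    out = apply_pose(pts, pose, anchor=rng.normal(size=3))
    assert np.abs(pdist(out) - pdist(pts)).max() < 1e-9


def test_apply_pose_scales_distances(rng):
    pts = rng.normal(size=(6, 3))
    pose = Pose(scale=2.5)
    out = apply_pose(pts, pose, anchor=pts[0])
    assert pdist(out) == pytest.approx(2.5 * pdist(pts))


def test_interpolate_pose_endpoints_and_midpoint():
    a = Pose(translation=np.zeros(3))
    b = Pose(translation=np.array([10.0, 0, 0]))
    assert interpolate_pose(a, b, 0.0).translation == pytest.approx(a.translation)
    assert interpolate_pose(a, b, 1.0).translation == pytest.approx(b.translation)
    mid = interpolate_pose(a, b, 0.5)
    assert mid.translation == pytest.approx([5.0, 0, 0])
    with pytest.raises(ValidationError):
        interpolate_pose(a, b, 1.5)


def test_interpolate_pose_shortest_arc():
    rot = Rotation.from_euler("z", 90, degrees=True)
    a = Pose.identity()
    b = Pose.from_rotation(rot)
    half = interpolate_pose(a, b, 0.5)
    expected = Rotation.from_euler("z", 45, degrees=True)
    assert half.matrix == pytest.approx(expected.as_matrix(), abs=1e-12)


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

def test_assemble_scene_anchors_at_translation(lys_glu):
    lys, glu = lys_glu
    t = np.array([7.0, -3.0, 2.0])
    scene = assemble_scene([
        AnchoredMolecule(lys, 0, Pose.identity(), "lys"),
        AnchoredMolecule(glu, 0, Pose(translation=t), "glu"),
    ])
    assert scene["lys"].world_coords[0] == pytest.approx(np.zeros(3), abs=1e-9)
    assert scene["glu"].world_coords[0] == pytest.approx(t, abs=1e-9)


def test_assemble_scene_separation_bound(lys_glu):
    """Two molecules 40 A apart cannot approach closer than 40 minus radii."""
    lys, glu = lys_glu
    scene = assemble_scene([
        AnchoredMolecule(lys, 0, Pose.identity(), "a"),
        AnchoredMolecule(glu, 0, Pose(translation=np.array([40.0, 0, 0])), "b"),
    ])
    diam_a = pdist(scene["a"].world_coords).max()
    diam_b = pdist(scene["b"].world_coords).max()
    d = np.linalg.norm(scene["a"].world_coords[:, None, :]
                       - scene["b"].world_coords[None, :, :], axis=2)
    assert d.min() >= 40.0 - diam_a - diam_b


def test_assemble_scene_continuity(lys_glu, rng):
    lys, _ = lys_glu
    pose = Pose.from_rotation(random_rotation(rng), np.array([1.0, 2.0, 3.0]))
    before = assemble_scene([AnchoredMolecule(lys, 2, pose, "m")])["m"].world_coords
    nudged = Pose(pose.quaternion, pose.translation + 1e-12, pose.scale)
    after = assemble_scene([AnchoredMolecule(lys, 2, nudged, "m")])["m"].world_coords
    assert np.abs(after - before).max() < 1e-9


def test_assemble_scene_rejects_bad_anchor(lys_glu):
    lys, _ = lys_glu
    with pytest.raises(ValidationError):
        AnchoredMolecule(lys, 99, Pose.identity(), "m")


def test_scene_ignores_zoom(lys_glu):
    """Display zoom never reaches physics coordinates."""
    lys, _ = lys_glu
    plain = assemble_scene([AnchoredMolecule(lys, 0, Pose.identity(), "m")])
    zoomed = assemble_scene([AnchoredMolecule(lys, 0, Pose(scale=3.0), "m")])
    assert zoomed["m"].world_coords == pytest.approx(plain["m"].world_coords)


# ---------------------------------------------------------------------------
# SAXS profile and contact-table files
# ---------------------------------------------------------------------------

def test_saxs_profile_roundtrip(tmp_path, rng):
    q = np.linspace(0.01, 0.5, 40)
    prof = SAXSProfile(q, rng.uniform(1, 100, size=40), rng.uniform(0.1, 1, size=40))
    path = tmp_path / "prof.dat"
    write_saxs_profile(prof, path)
    back = read_saxs_profile(path)
    assert back.q == pytest.approx(prof.q, abs=1e-12)
    assert back.intensity == pytest.approx(prof.intensity, rel=1e-12)
    assert back.sigma == pytest.approx(prof.sigma, rel=1e-12)


def test_read_saxs_profile_formats(tmp_path):
    p = tmp_path / "p.dat"
    p.write_text("#q I\n0.01 100 1\n0.02 90 1\n0.03 80 1\n")
    prof = read_saxs_profile(p)
    assert len(prof) == 3 and prof.sigma is not None
    p.write_text("0.01,100\n0.02,90\n")          # comma-delimited, 2 columns
    assert read_saxs_profile(p).sigma is None
    p.write_text("-0.01 5\n0.01 100\n")           # non-positive q dropped
    assert len(read_saxs_profile(p)) == 1
    p.write_text("0.02 90\n0.01 100\n")           # unsorted -> sorted
    assert list(read_saxs_profile(p).q) == [0.01, 0.02]
    p.write_text("0.01\n")
    with pytest.raises(FormatError):
        read_saxs_profile(p)


def test_read_contact_table(tmp_path):
    path = tmp_path / "contacts.tsv"
    path.write_text("A 10 B 20 high\nA 11 B 21 low\n")
    contacts = read_contact_table(path)
    assert len(contacts) == 2
    assert contacts[0].tier == "high"
    assert contacts[0].residue_a == ("A", 10)
    assert contacts[0].residue_b == ("B", 20)

    path.write_text("")
    assert read_contact_table(path) == []

    # numeric scores binned by the configured thresholds
    path.write_text("A 1 B 2 0.95\nA 3 B 4 0.91\nA 5 B 6 0.3\n")
    binned = read_contact_table(path, high_threshold=0.9)
    tiers = [c.tier for c in binned]
    assert tiers.count("high") == 2 and tiers.count("low") == 1

    path.write_text("A 1 B 2 nonsense\n")
    with pytest.raises(FormatError):
        read_contact_table(path)


def test_pose_trajectory_roundtrip(tmp_path, rng):
    frames = []
    for _ in range(3):
        frames.append({
            "a": Pose.from_rotation(random_rotation(rng), rng.normal(size=3)),
            "b": Pose(translation=rng.normal(size=3), scale=2.0),
        })
    path = tmp_path / "traj.poses"
    write_pose_trajectory(frames, path)
    back = read_pose_trajectory(path)
    assert len(back) == 3
    for orig, got in zip(frames, back):
        for key in orig:
            assert got[key].translation == pytest.approx(orig[key].translation)
            assert np.abs(got[key].quaternion) == pytest.approx(
                np.abs(orig[key].quaternion), abs=1e-10)
            assert got[key].scale == pytest.approx(orig[key].scale)
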