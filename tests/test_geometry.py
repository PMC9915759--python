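"""Superposition, displacement, dihedrals and docking angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import atoms_chain, gly_chain
from tcrface.errors import ConfigError, IncompleteResidueError, PairingError
from tcrface.geometry import (
    dihedral,
    docking_angles,
    kabsch,
    residue_displacement,
    sidechain_chi_angles,
    sidechain_dihedral_delta,
    superpose,
    wrap_angle,
)
from tcrface.model import Atom, Chain, ChainRole, ComplexDefinition, Residue, StructureModel
from tcrface.synthetic import make_mock_complex


def place_by_internal(p1, p2, p3, bond, angle_deg, dihedral_deg):
    """Fourth atom position from bond length, bond angle and dihedral."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    b1 = p2 - p1
    b2 = p3 - p2
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    b2u = b2 / np.linalg.norm(b2)
    m = np.cross(n, b2u)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(dih),
         bond * np.sin(ang) * np.sin(dih)]
    )
    return p3 + d[0] * b2u + d[1] * m + d[2] * n


def ser_residue(chi1_deg, seq_id=1):
    n = np.array([-1.45, 0.0, 0.0])
    ca = np.zeros(3)
    cb = place_by_internal([0, 2.0, 0], n, ca, 1.53, 110.0, 120.0)
    og = place_by_internal(n, ca, cb, 1.42, 109.5, chi1_deg)
    return Residue(
        seq_id, "SER",
        [Atom(name="N", element="N", position=tuple(n)),
         Atom(name="CA", element="C", position=tuple(ca)),
         Atom(name="CB", element="C", position=tuple(cb)),
         Atom(name="OG", element="O", position=tuple(og))],
    )


class TestKabsch:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(0)
        spec = [(i + 1, "GLY", "CA", "C", tuple(p))
                for i, p in enumerate(rng.normal(size=(10, 3)) * 5)]
        m = StructureModel("m", [atoms_chain("A", spec)])
        sup = superpose(m, m)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_applied_rigid_motion(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([3.0, -1.0, 7.0])
        sup = kabsch(P, P @ R.T + t)
        assert sup.rmsd < 1e-10
        np.testing.assert_allclose(sup.rotation, R, atol=1e-6)
        np.testing.assert_allclose(sup.translation, t, atol=1e-6)

    def test_rigid_motion_invariance_of_rmsd(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(15, 3))
        Q = P + rng.normal(scale=0.3, size=P.shape)
        base = kabsch(P, Q).rmsd
        R = Rotation.random(random_state=5).as_matrix()
        moved = kabsch(P @ R.T + [5, 5, 5], Q).rmsd
        assert moved == pytest.approx(base, abs=1e-6)

    def test_optimality_against_random_rotations(self):
        rng = np.random.default_rng(6)
        P = rng.normal(size=(10, 3))
        Q = P + rng.normal(scale=0.5, size=P.shape)
        best = kabsch(P, Q).rmsd
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        for R in Rotation.random(200, random_state=7).as_matrix():
            trial = np.sqrt((((Pc @ R.T) - Qc) ** 2).sum() / len(P))
            assert best <= trial + 1e-12

    def test_count_mismatch_and_degenerate_raise(self):
        with pytest.raises(PairingError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(PairingError, match="degenerate"):
            kabsch(line, line)
        with pytest.raises(PairingError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDisplacement:
    def test_identical_structures_zero(self):
        m = StructureModel("m", [gly_chain("A", 6)])
        rows, problems = residue_displacement(m, m)
        assert problems == []
        assert all(r["displacement"] == pytest.approx(0.0) for r in rows)

    def test_single_translated_residue(self):
        ref = StructureModel("r", [gly_chain("A", 6)])
        mob = StructureModel("m", [gly_chain("A", 6)])
        res = mob.chain("A").residues[3]
        atom = res.atoms[0]
        res.atoms[0] = Atom(name=atom.name, element=atom.element,
                            position=(atom.position[0], atom.position[1] + 5.0,
                                      atom.position[2]))
        rows, _ = residue_displacement(mob, ref)
        by_seq = {r["seq_id"]: r["displacement"] for r in rows}
        assert by_seq[4] == pytest.approx(5.0)
        assert all(v == pytest.approx(0.0) for s, v in by_seq.items() if s != 4)

    def test_name_mismatch_reported_not_skipped(self):
        ref = StructureModel("r", [gly_chain("A", 4)])
        mob_chain = gly_chain("A", 4)
        r = mob_chain.residues[1]
        mob_chain.residues[1] = Residue(r.seq_id, "ALA", r.atoms)
        mob = StructureModel("m", [mob_chain])
        rows, problems = residue_displacement(mob, ref)
        assert len(rows) == 3
        assert any("mismatch" in p for p in problems)


class TestDihedrals:
    @pytest.mark.parametrize("target", [-120.0, -60.0, 0.0, 60.0, 175.0])
    def test_constructed_dihedral_recovered(self, target):
        p0, p1, p2 = [0, 1.4, 0], [0, 0, 0], [1.5, 0, 0]
        p3 = place_by_internal(p0, p1, p2, 1.5, 109.0, target)
        assert dihedral(p0, p1, p2, p3) == pytest.approx(target, abs=1e-6)

    def test_identical_rotamer_zero_delta(self):
        out = sidechain_dihedral_delta(ser_residue(-65.0), ser_residue(-65.0))
        assert out["max_abs_delta"] == pytest.approx(0.0, abs=1e-9)

    def test_chi1_rotation_recovered(self):
        out = sidechain_dihedral_delta(ser_residue(-5.0), ser_residue(-65.0))
        assert out["delta"][0] == pytest.approx(60.0, abs=1e-3)

    def test_wrap_through_180(self):
        assert wrap_angle(-179.0 - 179.0) == pytest.approx(2.0)
        out = sidechain_dihedral_delta(ser_residue(179.0), ser_residue(-179.0))
        assert abs(out["delta"][0]) == pytest.approx(2.0, abs=1e-3)

    def test_missing_sidechain_atom_raises(self):
        res = ser_residue(-65.0)
        broken = Residue(1, "SER", res.atoms[:3])  # no OG
        with pytest.raises(IncompleteResidueError):
            sidechain_chi_angles(broken)

    def test_glycine_has_no_chi(self):
        res = Residue(1, "GLY", [Atom(name="CA", element="C", position=(0, 0, 0))])
        assert sidechain_chi_angles(res) == []


class TestDockingAngles:
    @pytest.mark.parametrize("crossing,incident", [
        (45.0, 0.0), (90.0, 0.0), (30.0, 30.0), (57.49, 13.13), (120.0, 5.0),
    ])
    def test_constructed_geometry_recovered(self, crossing, incident):
        cx, _ = make_mock_complex(crossing, incident, contact_distance=None)
        geom = docking_angles(cx)
        assert geom.crossing_angle == pytest.approx(crossing, abs=0.1)
        assert geom.incident_angle == pytest.approx(incident, abs=0.1)

    def test_rigid_motion_invariance(self):
        cx, _ = make_mock_complex(57.49, 13.13, contact_distance=None)
        base = docking_angles(cx)
        R = Rotation.random(random_state=8).as_matrix()
        moved_model = cx.model.transformed(R, np.array([10.0, -4.0, 2.0]))
        moved = ComplexDefinition(moved_model, dict(cx.roles))
        geom = docking_angles(moved)
        assert geom.crossing_angle == pytest.approx(base.crossing_angle, abs=1e-6)
        assert geom.incident_angle == pytest.approx(base.incident_angle, abs=1e-6)

    def test_missing_roles_rejected(self):
        cx, _ = make_mock_complex(contact_distance=None)
        roles = dict(cx.roles)
        model = StructureModel(
            "m", [c for c in cx.model.chains if c.chain_id != "B"]
        )
        del roles["B"]
        with pytest.raises(ConfigError):
            docking_angles(ComplexDefinition(model, roles))
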