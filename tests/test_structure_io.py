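"""Structure parsing, role assignment and selection."""

import numpy as np
import pytest

from conftest import ALTLOC_PDB, MINIMAL_PDB, gly_chain
from tcrface.errors import (
    FormatError,
    ParseError,
    RoleAssignmentError,
    SelectionError,
)
from tcrface.model import ChainRole, StructureModel
from tcrface.structure_io import (
    assign_roles,
    parse_structure,
    read_complex_config,
    select,
    write_structure,
)


class TestParsing:
    def test_minimal_single_atom(self):
        m = parse_structure(MINIMAL_PDB, format="pdb")
        assert len(m.chains) == 1
        assert len(m.chains[0]) == 1
        (atom,) = m.chains[0].residues[0].atoms
        assert atom.name == "CA" and atom.element == "C"
        assert atom.position == (10.0, 20.0, 30.0)
        assert atom.b_factor == 15.0

    def test_altloc_keeps_highest_occupancy_then_first_letter(self):
        m = parse_structure(ALTLOC_PDB, format="pdb")
        ala = m.chain("A").residue(1)
        # hydrogens dropped, one conformer per altloc group
        assert [a.name for a in ala.atoms] == ["N", "CA", "CB"]
        assert ala.atom("CA").occupancy == pytest.approx(0.6)  # higher occ wins
        assert ala.atom("CA").altloc == "A"
        assert ala.atom("CB").altloc == "A"  # tie broken by first letter

    def test_hydrogens_dropped_waters_kept(self):
        m = parse_structure(ALTLOC_PDB, format="pdb")
        names = [a.name for _, _, a in m.iter_atoms()]
        assert "H" not in names
        assert m.chain("W").residues[0].is_water

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        heavy = gly_chain("H", 20, b_factor=33.25)
        model = StructureModel("rt", [heavy])
        path = tmp_path / "rt.pdb"
        write_structure(model, path)
        back = parse_structure(path)
        assert back.n_atoms == model.n_atoms
        np.testing.assert_allclose(back.coords(), model.coords(), atol=1e-3)
        assert back.chain("H").residues[5].atoms[0].b_factor == pytest.approx(
            33.25, abs=1e-2
        )

    def test_mmcif_roundtrip(self, tmp_path):
        model = StructureModel("rt", [gly_chain("H", 7)])
        path = tmp_path / "rt.cif"
        write_structure(model, path)
        back = parse_structure(path)
        np.testing.assert_allclose(back.coords(), model.coords(), atol=1e-3)

    def test_garbage_raises_parse_error(self):
        with pytest.raises(ParseError):
            parse_structure("this is not a structure\nat all\n", format="pdb")

    def test_missing_file_raises(self):
        with pytest.raises(ParseError):
            parse_structure("/no/such/file.pdb")

    def test_unknown_format_rejected(self):
        with pytest.raises(FormatError):
            parse_structure(MINIMAL_PDB, format="xyz")


class TestRoleAssignment:
    def test_length_heuristics(self):
        model = StructureModel(
            "m",
            [gly_chain("H", 275), gly_chain("B", 99, origin=(0, 50, 0)),
             gly_chain("P", 9, origin=(0, 100, 0))],
        )
        cx = assign_roles(model)
        assert cx.roles == {
            "H": ChainRole.MHC_HEAVY, "B": ChainRole.B2M, "P": ChainRole.PEPTIDE
        }

    def test_two_unequal_leftovers_become_tcr(self):
        model = StructureModel(
            "m",
            [gly_chain("H", 275), gly_chain("B", 99, origin=(0, 50, 0)),
             gly_chain("P", 9, origin=(0, 100, 0)),
             gly_chain("D", 200, origin=(0, 150, 0)),
             gly_chain("E", 243, origin=(0, 200, 0))],
        )
        cx = assign_roles(model)
        assert cx.roles["D"] == ChainRole.TCR_ALPHA  # shorter
        assert cx.roles["E"] == ChainRole.TCR_BETA  # longer

    def test_equal_length_leftovers_raise(self):
        model = StructureModel(
            "m", [gly_chain("X", 200), gly_chain("Y", 200, origin=(0, 50, 0))]
        )
        with pytest.raises(RoleAssignmentError, match="ambiguous"):
            assign_roles(model)

    def test_overrides_win(self):
        model = StructureModel(
            "m", [gly_chain("X", 200), gly_chain("Y", 200, origin=(0, 50, 0))]
        )
        cx = assign_roles(model, {"X": "tcr_beta", "Y": "tcr_alpha"})
        assert cx.roles["X"] == ChainRole.TCR_BETA

    def test_water_chain(self):
        pdb = "HETATM    1  O   HOH W   1       0.000   0.000   0.000  1.00 20.00           O\nEND\n"
        model = parse_structure(pdb, format="pdb")
        cx = assign_roles(model)
        assert cx.roles["W"] == ChainRole.WATER


class TestSelect:
    @pytest.fixture
    def model(self):
        from conftest import atoms_chain

        spec = []
        for i in range(1, 10):
            for k, (name, el) in enumerate(
                (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
            ):
                spec.append((i, "ALA", name, el, (3.8 * i, 0.5 * k, 0.0)))
        return StructureModel("sel", [atoms_chain("A", spec)])

    def test_select_all_is_identity(self, model):
        sub = select(model, "all")
        assert sub.n_atoms == model.n_atoms
        np.testing.assert_allclose(sub.coords(), model.coords())

    def test_residue_range(self, model):
        sub = select(model, "chain=A resi=1-4")
        assert len(sub.chain("A")) == 4

    def test_ca_only(self, model):
        sub = select(model, "name=CA")
        assert sub.n_atoms == 9
        assert all(a.name == "CA" for _, _, a in sub.iter_atoms())

    def test_idempotent_and_composable(self, model):
        s = "chain=A resi=2-6 name=CA"
        once = select(model, s)
        twice = select(once, s)
        np.testing.assert_allclose(once.coords(), twice.coords())
        assert once.n_atoms == twice.n_atoms == 5

    def test_empty_selection_raises(self, model):
        with pytest.raises(SelectionError):
            select(model, "chain=Z")

    def test_malformed_selector(self, model):
        with pytest.raises(SelectionError):
            select(model, "resi=1-4 frobnicate")


def test_complex_config_roundtrip(tmp_path):
    cfg = tmp_path / "complex.cfg"
    cfg.write_text(
        "# roles\n"
        "role.A = mhc_heavy\n"
        "role.E = tcr_alpha\n"
        "cdr.tcr_alpha.CDR3 = 95-107\n"
    )
    parsed = read_complex_config(cfg)
    assert parsed["roles"] == {"A": "mhc_heavy", "E": "tcr_alpha"}
    assert parsed["cdr_ranges"]["tcr_alpha"]["CDR3"] == (95, 107)
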