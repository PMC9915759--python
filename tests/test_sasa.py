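"""Shrake-Rupley engine against analytic and third-party oracles."""

import math

import numpy as np
import pytest

from conftest import atoms_chain, gly_chain
from tcrface.errors import ConfigError, MissingRadiusError
from tcrface.model import (
    Atom,
    Chain,
    ChainRole,
    ComplexDefinition,
    Residue,
    StructureModel,
)
from tcrface.sasa import (
    SASAParams,
    buried_surface,
    compute_sasa,
    fibonacci_sphere,
    residue_surface_terms,
    vdw_radius,
)
from tcrface.synthetic import (
    make_sphere_cluster,
    numeric_accessible_area,
    two_sphere_accessible_areas,
)

PROBE = 1.4


def cluster_params(ledger, n_points=960):
    return SASAParams(probe_radius=ledger["probe_radius"], n_points=n_points,
                      radius_set=ledger["radius_set"])


class TestSphereLattice:
    def test_points_are_unit_and_deterministic(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(960))

    def test_isolated_sphere_exact_within_lattice_bound(self):
        model, ledger = make_sphere_cluster([[0, 0, 0]], radii=1.7)
        for n in (100, 960, 4000):
            res = compute_sasa(model, cluster_params(ledger, n))
            exact = 4 * math.pi * (1.7 + PROBE) ** 2
            assert abs(res.total - exact) / exact < 1.0 / math.sqrt(n)

    def test_two_distant_spheres_additive(self):
        model, ledger = make_sphere_cluster([[0, 0, 0], [50, 0, 0]], radii=1.7)
        res = compute_sasa(model, cluster_params(ledger))
        assert res.total == pytest.approx(2 * 4 * math.pi * 3.1**2, rel=1e-9)


class TestTwoSphereOracle:
    @pytest.mark.parametrize("d,r1,r2", [(2.0, 1.7, 1.7), (3.0, 1.7, 1.4),
                                         (1.2, 1.7, 1.7), (5.5, 1.9, 1.4)])
    def test_engine_matches_closed_form_within_1pct(self, d, r1, r2):
        model, ledger = make_sphere_cluster([[0, 0, 0], [d, 0, 0]], radii=[r1, r2])
        res = compute_sasa(model, cluster_params(ledger, n_points=2000))
        a1, a2 = two_sphere_accessible_areas([0, 0, 0], r1, [d, 0, 0], r2)
        per_atom = list(res.per_atom.values())
        assert per_atom[0] == pytest.approx(a1, rel=0.01)
        assert per_atom[1] == pytest.approx(a2, rel=0.01)

    def test_closed_form_matches_numeric_integration(self):
        # independent arbitration between the two oracles, 0.1%
        a1, _ = two_sphere_accessible_areas([0, 0, 0], 1.7, [2.0, 0, 0], 1.7)
        num = numeric_accessible_area([0, 0, 0], 1.7, [([2.0, 0, 0], 1.7)])
        assert num == pytest.approx(a1, rel=1e-3)


class TestInvariants:
    def test_occluder_never_increases_sasa(self):
        rng = np.random.default_rng(7)
        centers = rng.uniform(0, 12, size=(15, 3))
        model, ledger = make_sphere_cluster([[30, 30, 30]], radii=1.7)
        spec = [(i + 1, "ALA", "CA", "C", tuple(c)) for i, c in enumerate(centers)]
        base_model = StructureModel("b", [atoms_chain("A", spec)])
        params = SASAParams(n_points=960)
        base = compute_sasa(base_model, params)
        extra = spec + [(99, "ALA", "CA", "C", tuple(centers[0] + [2.5, 0, 0]))]
        more = compute_sasa(StructureModel("b", [atoms_chain("A", extra)]), params)
        for key, area in base.per_atom.items():
            assert more.per_atom[key] <= area + 1e-9

    def test_per_residue_and_chain_sums_reconcile(self):
        model = StructureModel(
            "m", [gly_chain("A", 8), gly_chain("B", 5, origin=(0, 8, 0))]
        )
        res = compute_sasa(model, SASAParams(n_points=480))
        assert sum(res.per_residue.values()) == pytest.approx(res.total, abs=1e-9)
        assert sum(res.per_chain.values()) == pytest.approx(res.total, abs=1e-9)

    def test_convergence_with_lattice_density(self):
        rng = np.random.default_rng(3)
        spec = [(i + 1, "ALA", "CA", "C", tuple(p))
                for i, p in enumerate(rng.uniform(0, 10, size=(20, 3)))]
        model = StructureModel("m", [atoms_chain("A", spec)])
        coarse = compute_sasa(model, SASAParams(n_points=960)).total
        fine = compute_sasa(model, SASAParams(n_points=4000)).total
        assert abs(fine - coarse) / fine < 0.005

    def test_missing_radius_names_the_atom(self):
        res = Residue(1, "LIG", [Atom(name="FE1", element="Fe", position=(0, 0, 0))])
        model = StructureModel("m", [Chain("A", [res])])
        with pytest.raises(MissingRadiusError, match="FE1"):
            compute_sasa(model, SASAParams())

    def test_radius_table_carbon_classes(self):
        assert vdw_radius("PHE", "CZ", "C") == 1.76  # aromatic
        assert vdw_radius("ALA", "CB", "C") == 1.87  # tetrahedral
        assert vdw_radius("ALA", "C", "C") == 1.76  # carbonyl
        assert vdw_radius("ALA", "N", "N") == 1.65
        with pytest.raises(ConfigError):
            vdw_radius("ALA", "CA", "C", radius_set="nope")


class TestSurfaceTerms:
    def test_isolated_single_residue_chain_has_zero_bsa(self):
        model = StructureModel("m", [gly_chain("P", 1)])
        cx = ComplexDefinition(model, {"P": ChainRole.PEPTIDE})
        terms = residue_surface_terms(cx, ("P", 1))
        assert terms.bsa == pytest.approx(0.0, abs=1e-9)
        assert terms.asa == pytest.approx(terms.tsa, rel=1e-9)

    def test_buried_residue_terms_ordering(self):
        # peptide residue sandwiched inside an occluding partner chain
        pep = gly_chain("P", 3, origin=(0, 0, 0), step=(3.5, 0, 0))
        wall_spec = [(i + 1, "GLY", "CA", "C", (3.5 * (i % 3), 3.0, 2.0 * (i // 3)))
                     for i in range(6)]
        model = StructureModel("m", [pep, atoms_chain("M", wall_spec)])
        cx = ComplexDefinition(
            model, {"P": ChainRole.PEPTIDE, "M": ChainRole.MHC_HEAVY}
        )
        terms = residue_surface_terms(cx, "p2")
        assert terms.bsa > 0
        assert terms.bsa <= terms.asa <= terms.tsa + 1e-6
        assert terms.sasa_complex == pytest.approx(terms.asa - terms.bsa, abs=1e-9)

    def test_peptide_ordinal_selector(self):
        pep = gly_chain("P", 9, start_seq=68)  # author numbering offset
        model = StructureModel("m", [pep])
        cx = ComplexDefinition(model, {"P": ChainRole.PEPTIDE})
        # p5 is the 5th residue regardless of author numbering
        t_ord = residue_surface_terms(cx, "p5")
        t_seq = residue_surface_terms(cx, ("P", 72))
        assert t_ord.tsa == pytest.approx(t_seq.tsa)


class TestBuriedSurface:
    def test_separated_components_bury_nothing(self):
        model = StructureModel(
            "m", [gly_chain("T", 4), gly_chain("M", 4, origin=(0, 50, 0))]
        )
        cx = ComplexDefinition(
            model, {"T": ChainRole.TCR_ALPHA, "M": ChainRole.MHC_HEAVY}
        )
        area = buried_surface(cx, ("tcr_alpha",), ("mhc_heavy",))
        assert area.side_a_total == pytest.approx(0.0, abs=1e-9)
        assert area.side_b_total == pytest.approx(0.0, abs=1e-9)

    def test_two_component_cluster_matches_pairwise_oracle(self):
        # chains interleaved so every overlap is across the interface
        centers = [[0, 0, 0], [0, 0, 8], [0, 0, 16],
                   [3.0, 0, 0], [3.0, 0, 8], [3.0, 0, 16]]
        chain_ids = ["T", "T", "T", "M", "M", "M"]
        model, ledger = make_sphere_cluster(centers, radii=1.7, chain_ids=chain_ids)
        cx = ComplexDefinition(
            model, {"T": ChainRole.TCR_ALPHA, "M": ChainRole.MHC_HEAVY}
        )
        params = cluster_params(ledger, n_points=2000)
        area = buried_surface(cx, ("tcr_alpha",), ("mhc_heavy",), params)
        # analytic: each cross pair buries one cap on each side
        full = 4 * math.pi * 3.1**2
        a1, _ = two_sphere_accessible_areas([0, 0, 0], 1.7, [3.0, 0, 0], 1.7)
        expected_side = 3 * (full - a1)
        assert area.side_a_total == pytest.approx(expected_side, rel=0.01)
        assert area.side_b_total == pytest.approx(expected_side, rel=0.01)

    def test_sides_must_bipartition(self):
        model = StructureModel(
            "m", [gly_chain("T", 4), gly_chain("M", 4, origin=(0, 50, 0)),
                  gly_chain("P", 4, origin=(0, 100, 0))]
        )
        cx = ComplexDefinition(
            model, {"T": ChainRole.TCR_ALPHA, "M": ChainRole.MHC_HEAVY,
                    "P": ChainRole.PEPTIDE}
        )
        with pytest.raises(ConfigError, match="bipartition"):
            buried_surface(cx, ("tcr_alpha",), ("mhc_heavy",))
        with pytest.raises(ConfigError, match="overlap"):
            buried_surface(cx, ("tcr_alpha", "peptide"),
                           ("mhc_heavy", "peptide"))


def test_cross_check_against_biotite():
    """Independent third-party Shrake-Rupley on the same coordinates."""
    import biotite.structure as struc

    rng = np.random.default_rng(11)
    centers = rng.uniform(0, 14, size=(25, 3))
    spec = [(i + 1, "UNK", "C", "C", tuple(c)) for i, c in enumerate(centers)]
    model = StructureModel("cluster", [atoms_chain("X", spec)])
    ours = compute_sasa(
        model, SASAParams(n_points=2000, radius_set={"C": 1.7})
    ).total

    arr = struc.AtomArray(len(centers))
    arr.coord = centers.astype(np.float32)
    arr.chain_id[:] = "X"
    arr.res_id[:] = np.arange(1, len(centers) + 1)
    arr.res_name[:] = "UNK"
    arr.atom_name[:] = "C"
    arr.element[:] = "C"
    theirs = float(
        struc.sasa(arr, probe_radius=1.4, point_number=2000,
                   vdw_radii=np.full(len(centers), 1.7)).sum()
    )
    assert ours == pytest.approx(theirs, rel=0.02)
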