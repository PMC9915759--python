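"""Rigid-body comparison and TCR docking geometry.

Superposition is the closed-form least-squares (Kabsch) solution via SVD,
with the reflection case handled so the result is always a proper
rotation. Docking geometry follows the common literature convention for
class-I TCR complexes:

* peptide axis — best-fit line through the peptide Calpha atoms,
  oriented N- to C-terminus (p1 -> pN);
* TCR axis — the line connecting the V-alpha and V-beta domain centres
  (midpoint of each domain's conserved intra-domain disulfide cysteines,
  falling back to the V-domain Calpha centroid when the cysteines are
  not found);
* platform plane — least-squares plane through the Calpha atoms of the
  MHC alpha1/alpha2 helices (heavy-chain author residues 50-86 and
  138-176 by default, configurable);
* crossing angle — angle between the TCR axis and the peptide axis
  after projecting both into the platform plane, in [0, 180);
* incident angle — out-of-plane tilt of the TCR axis relative to the
  platform plane, in [0, 90].

Published structure reports rarely state the convention they used, so
every piece of the definition is configurable and printed angles are
matched within a tolerance, not exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, IncompleteResidueError, PairingError
from .model import Chain, ChainRole, ComplexDefinition, Residue, StructureModel
from .structure_io import select

__all__ = [
    "Superposition",
    "DockingConvention",
    "DockingGeometry",
    "kabsch",
    "superpose",
    "residue_displacement",
    "dihedral",
    "sidechain_chi_angles",
    "sidechain_dihedral_delta",
    "wrap_angle",
    "docking_angles",
]


# ---------------------------------------------------------------------------
# Superposition


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid motion ``x -> R x + t`` mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1")
        if self.rmsd < 0:
            raise ValueError("negative rmsd")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def apply(self, model: StructureModel) -> StructureModel:
        return model.transformed(self.rotation, self.translation)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired coordinate sets.

    Both arrays are (n, 3) with row i of ``mobile`` paired to row i of
    ``reference``; n >= 3 and the points must not be collinear.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise PairingError(f"paired coordinate shapes differ: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise PairingError(f"need >= 3 paired atoms, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise PairingError("degenerate (collinear) geometry: rotation not determined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _selected_coords(model: StructureModel, selector) -> np.ndarray:
    return select(model, selector).coords()


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    atom_selector: str | Mapping = "name=CA",
) -> Superposition:
    """Kabsch superposition over atoms picked by ``atom_selector``.

    Atoms pair up in iteration (file) order; the two selections must
    yield equal counts.
    """
    P = _selected_coords(mobile, atom_selector)
    Q = _selected_coords(reference, atom_selector)
    if P.shape[0] != Q.shape[0]:
        raise PairingError(
            f"selector {atom_selector!r} yields {P.shape[0]} atoms in mobile "
            f"but {Q.shape[0]} in reference"
        )
    return kabsch(P, Q)


# ---------------------------------------------------------------------------
# Per-residue displacement


def residue_displacement(
    mobile: StructureModel,
    reference: StructureModel,
    chain_map: Mapping[str, str] | None = None,
) -> tuple[list[dict], list[str]]:
    """Calpha-Calpha distance per matched residue (structures assumed to
    be in the same frame, e.g. after :func:`superpose` + ``apply``).

    Residues pair by ordinal within mapped chains and must agree on the
    residue name; mismatches are reported in the second return value,
    never silently skipped.
    """
    if chain_map is None:
        shared = [c for c in mobile.chain_ids if c in set(reference.chain_ids)]
        if not shared:
            raise PairingError("no shared chain ids and no chain_map given")
        chain_map = {c: c for c in shared}
    rows: list[dict] = []
    problems: list[str] = []
    for cm, cr in chain_map.items():
        try:
            chain_m, chain_r = mobile.chain(cm), reference.chain(cr)
        except KeyError as exc:
            raise PairingError(str(exc)) from exc
        n = min(len(chain_m), len(chain_r))
        if len(chain_m) != len(chain_r):
            problems.append(
                f"chain {cm}->{cr}: residue counts differ "
                f"({len(chain_m)} vs {len(chain_r)}); comparing first {n}"
            )
        for rm, rr in zip(chain_m.residues[:n], chain_r.residues[:n]):
            if rm.name != rr.name:
                problems.append(
                    f"chain {cm}->{cr}: residue name mismatch "
                    f"{rm.label} vs {rr.label}"
                )
                continue
            if not (rm.has_atom("CA") and rr.has_atom("CA")):
                continue
            d = float(np.linalg.norm(rm.atom("CA").xyz - rr.atom("CA").xyz))
            rows.append(
                {"chain": cm, "seq_id": rm.seq_id, "name": rm.name,
                 "displacement": d}
            )
    return rows, problems


# ---------------------------------------------------------------------------
# Side-chain dihedrals

# chi_k is defined by four consecutive side-chain heavy atoms; the table
# lists atom quadruples per residue type.
_CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = float(v @ w)
    y = float(np.cross(b1, v) @ w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def wrap_angle(delta: float) -> float:
    """Wrap an angle difference into (-180, 180] degrees."""
    d = float(delta) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


def sidechain_chi_angles(res: Residue) -> list[float]:
    """chi1..chi_n of one residue from standard atom quadruples.

    Raises :class:`IncompleteResidueError` if a required heavy atom is
    missing; GLY/ALA have no chi angles (empty list).
    """
    quads = _CHI_ATOMS.get(res.name, [])
    angles: list[float] = []
    for quad in quads:
        try:
            pts = [res.atom(a).xyz for a in quad]
        except KeyError as exc:
            raise IncompleteResidueError(
                f"{res.label}: missing side-chain atom for chi{len(angles)+1}: {exc}"
            ) from exc
        angles.append(dihedral(*pts))
    return angles


def sidechain_dihedral_delta(res_a: Residue, res_b: Residue) -> dict:
    """Per-chi angle change between two conformers of the same residue.

    Deltas are wrapped to (-180, 180]; the summary includes the maximum
    absolute change, the quantity usually quoted for a side-chain
    rotation between bound and unbound structures.
    """
    if res_a.name != res_b.name:
        raise PairingError(f"residue name mismatch: {res_a.label} vs {res_b.label}")
    chi_a = sidechain_chi_angles(res_a)
    chi_b = sidechain_chi_angles(res_b)
    deltas = [wrap_angle(a - b) for a, b in zip(chi_a, chi_b)]
    return {
        "residue": res_a.label,
        "chi_a": chi_a,
        "chi_b": chi_b,
        "delta": deltas,
        "max_abs_delta": max((abs(d) for d in deltas), default=0.0),
    }


# ---------------------------------------------------------------------------
# Docking geometry


@dataclass(frozen=True)
class DockingConvention:
    """Configurable pieces of the docking-angle definition."""

    helix_ranges: tuple[tuple[int, int], ...] = ((50, 86), (138, 176))
    v_domain_max_seq_id: int = 120
    use_disulfide_midpoints: bool = True


@dataclass(frozen=True)
class DockingGeometry:
    """Crossing/incident angles with the axes that produced them."""

    crossing_angle: float
    incident_angle: float
    tcr_axis: np.ndarray
    peptide_axis: np.ndarray
    platform_normal: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.tcr_axis, self.peptide_axis, self.platform_normal):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("axes must be unit vectors")
        if not (0.0 <= self.crossing_angle < 180.0):
            raise ValueError(f"crossing angle out of [0,180): {self.crossing_angle}")
        if not (0.0 <= self.incident_angle <= 90.0):
            raise ValueError(f"incident angle out of [0,90]: {self.incident_angle}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ConfigError("zero-length axis vector")
    return v / n


def _fit_line(points: np.ndarray) -> np.ndarray:
    """Unit direction of the best-fit (total least squares) line."""
    centered = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    return _unit(Vt[0])


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through the points."""
    centered = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    return _unit(Vt[2])


def _v_domain_point(chain: Chain, convention: DockingConvention) -> np.ndarray:
    """Reference point of a TCR V domain.

    Midpoint of the SG atoms of the conserved intra-domain disulfide
    cysteines when exactly two are present in the V region; otherwise
    the Calpha centroid of the V region.
    """
    v_res = [r for r in chain.residues if r.seq_id <= convention.v_domain_max_seq_id]
    if not v_res:
        v_res = list(chain.residues)
    if convention.use_disulfide_midpoints:
        sg = [r.atom("SG").xyz for r in v_res if r.name == "CYS" and r.has_atom("SG")]
        if len(sg) == 2:
            return 0.5 * (sg[0] + sg[1])
    ca = [r.atom("CA").xyz for r in v_res if r.has_atom("CA")]
    if not ca:
        ca = [a.xyz for r in v_res for a in r.atoms]
    return np.mean(ca, axis=0)


def docking_angles(
    cx: ComplexDefinition,
    convention: DockingConvention | None = None,
) -> DockingGeometry:
    """Crossing and incident angle of a TCR over its pMHC platform."""
    convention = convention or DockingConvention()
    for role in (ChainRole.PEPTIDE, ChainRole.TCR_ALPHA, ChainRole.TCR_BETA,
                 ChainRole.MHC_HEAVY):
        if not cx.chains_with_role(role):
            raise ConfigError(f"docking geometry requires a {role.value} chain")

    pep = cx.peptide
    pep_ca = np.array([r.atom("CA").xyz for r in pep.residues if r.has_atom("CA")])
    if pep_ca.shape[0] < 3:
        raise ConfigError("peptide has fewer than 3 Calpha atoms")
    pep_axis = _fit_line(pep_ca)
    if pep_axis @ (pep_ca[-1] - pep_ca[0]) < 0:  # orient p1 -> pN
        pep_axis = -pep_axis

    heavy = cx.chains_with_role(ChainRole.MHC_HEAVY)[0]
    helix_ca = []
    for lo, hi in convention.helix_ranges:
        for r in heavy.residues:
            if lo <= r.seq_id <= hi and r.has_atom("CA"):
                helix_ca.append(r.atom("CA").xyz)
    if len(helix_ca) < 3:
        raise ConfigError(
            f"platform helix ranges {convention.helix_ranges} select fewer "
            "than 3 Calpha atoms on the MHC heavy chain"
        )
    normal = _fit_plane_normal(np.array(helix_ca))

    p_alpha = _v_domain_point(cx.chains_with_role(ChainRole.TCR_ALPHA)[0], convention)
    p_beta = _v_domain_point(cx.chains_with_role(ChainRole.TCR_BETA)[0], convention)
    tcr_axis = _unit(p_beta - p_alpha)

    # In-plane projections for the crossing angle.
    def project(v: np.ndarray) -> np.ndarray:
        return _unit(v - (v @ normal) * normal)

    cross = float(
        np.degrees(
            np.arccos(np.clip(project(tcr_axis) @ project(pep_axis), -1.0, 1.0))
        )
    )
    if cross >= 180.0:
        cross = 0.0
    incident = float(
        np.degrees(np.arcsin(np.clip(abs(tcr_axis @ normal), 0.0, 1.0)))
    )
    return DockingGeometry(
        crossing_angle=cross,
        incident_angle=incident,
        tcr_axis=tcr_axis,
        peptide_axis=pep_axis,
        platform_normal=normal,
    )
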