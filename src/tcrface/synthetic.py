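"""Synthetic structures and datasets with analytically known answers.

Everything the analysis modules compute — accessible areas, buried
areas, contacts, docking angles, B-factor statistics, dose-response
parameters — can be generated here with ground truth attached, so the
whole pipeline is testable without downloading any deposited structure.

Two independent oracles for surface areas are provided:

* :func:`two_sphere_accessible_areas` — the closed-form spherical-cap
  solution for a pair of probe-expanded spheres;
* :func:`numeric_accessible_area` — brute-force latitude/longitude
  quadrature over one sphere against arbitrary occluders.

Sphere-cluster fixtures enforce a *pairwise-only* overlap constraint
(no atom is occluded by two neighbours at once, checked via cap
geometry), which is exactly the regime where the closed form is additive
over pairs.

All generators are deterministic: fixed inputs (and seed, where one is
used) give byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dose_response import TitrationSeries, four_pl
from .errors import ConfigError, ValidationError
from .model import (
    Atom,
    Chain,
    ChainRole,
    ComplexDefinition,
    Residue,
    StructureModel,
)

__all__ = [
    "two_sphere_accessible_areas",
    "numeric_accessible_area",
    "make_sphere_cluster",
    "make_mock_complex",
    "make_bfactor_peptide",
    "make_titration",
    "write_fixture",
]

_ELEMENT_POOL = ["C", "N", "O", "S", "P"]


# ---------------------------------------------------------------------------
# Analytic oracles


def _cap_height(R_i: float, R_j: float, d: float) -> float | None:
    """Height of the cap cut from sphere i (radius R_i) by sphere j.

    Returns None when i is entirely swallowed by j; 0.0 when they do not
    overlap (or j lies entirely inside i).
    """
    if d >= R_i + R_j:
        return 0.0
    if d + R_i <= R_j:
        return None  # sphere i fully covered
    if d + R_j <= R_i:
        return 0.0  # j inside i: no surface of i covered
    x = (d * d + R_i * R_i - R_j * R_j) / (2.0 * d)
    return R_i - x


def two_sphere_accessible_areas(
    c1: Sequence[float], r1: float, c2: Sequence[float], r2: float,
    probe: float = 1.4,
) -> tuple[float, float]:
    """Closed-form accessible areas of two probe-expanded spheres.

    Spherical-cap subtraction: each sphere loses ``2 pi R h`` where h is
    the height of the cap cut off by the other expanded sphere.
    """
    R1, R2 = r1 + probe, r2 + probe
    d = float(np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)))
    areas = []
    for R_a, R_b in ((R1, R2), (R2, R1)):
        h = _cap_height(R_a, R_b, d)
        if h is None:
            areas.append(0.0)
        else:
            areas.append(4.0 * math.pi * R_a**2 - 2.0 * math.pi * R_a * h)
    return areas[0], areas[1]


def numeric_accessible_area(
    center: Sequence[float],
    radius: float,
    occluders: Sequence[tuple[Sequence[float], float]],
    probe: float = 1.4,
    n_theta: int = 600,
) -> float:
    """Accessible area of one probe-expanded sphere by direct quadrature.

    Latitude/longitude grid with sin(theta) weights — independent of the
    Shrake-Rupley point lattice and of the closed-form solution, so it
    can arbitrate between them. ``occluders`` are (center, vdw_radius)
    pairs, expanded by the same probe.
    """
    center = np.asarray(center, dtype=float)
    R = radius + probe
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    n_phi = 2 * n_theta
    phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
    st, ct = np.sin(theta), np.cos(theta)
    # Points grid: (n_theta, n_phi, 3)
    pts = np.empty((n_theta, n_phi, 3))
    pts[..., 0] = st[:, None] * np.cos(phi)[None, :]
    pts[..., 1] = st[:, None] * np.sin(phi)[None, :]
    pts[..., 2] = ct[:, None]
    pts = center + R * pts
    accessible = np.ones((n_theta, n_phi), dtype=bool)
    for c_j, r_j in occluders:
        c_j = np.asarray(c_j, dtype=float)
        R_j = r_j + probe
        d2 = ((pts - c_j) ** 2).sum(axis=-1)
        accessible &= d2 > R_j * R_j
    weights = st[:, None] * (math.pi / n_theta) * (2.0 * math.pi / n_phi)
    return float(R * R * (accessible * weights).sum())


# ---------------------------------------------------------------------------
# Sphere clusters


def _pairwise_only_check(centers: np.ndarray, R: np.ndarray) -> None:
    """Reject configurations where one sphere is occluded by two others
    whose caps intersect (the closed form is then no longer additive)."""
    n = len(centers)
    for i in range(n):
        caps = []  # (direction, angular radius) of each cap on sphere i
        for j in range(n):
            if i == j:
                continue
            d = float(np.linalg.norm(centers[j] - centers[i]))
            h = _cap_height(R[i], R[j], d)
            if h is None:
                raise ConfigError(
                    f"sphere {i} fully covered by sphere {j}; not pairwise-only"
                )
            if h <= 0.0:
                continue
            cos_alpha = 1.0 - h / R[i]
            alpha = math.acos(max(-1.0, min(1.0, cos_alpha)))
            caps.append(((centers[j] - centers[i]) / d, alpha))
        for a in range(len(caps)):
            for b in range(a + 1, len(caps)):
                u, alpha_a = caps[a]
                v, alpha_b = caps[b]
                gamma = math.acos(max(-1.0, min(1.0, float(u @ v))))
                if gamma < alpha_a + alpha_b:
                    raise ConfigError(
                        f"caps on sphere {i} intersect (pairwise-only "
                        "constraint violated); spread the centers out"
                    )


def make_sphere_cluster(
    centers: Sequence[Sequence[float]],
    radii: float | Sequence[float] = 1.7,
    probe: float = 1.4,
    chain_ids: Sequence[str] | None = None,
) -> tuple[StructureModel, dict]:
    """Pseudo-atom cluster with a closed-form accessible-area ledger.

    Each sphere becomes one single-atom UNK residue (standard ATOM
    records, so fixtures round-trip through the structure reader).
    Distinct radii map to distinct element symbols; the ledger carries
    the matching ``radius_set`` to hand to the SASA engine, the exact
    per-atom accessible areas, and the total.

    ``chain_ids`` optionally assigns each sphere to a chain (default:
    all in chain "X") — used to build two-component fixtures with a
    known buried interface.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ConfigError("centers must be (n, 3)")
    n = len(centers)
    radii_arr = np.full(n, float(radii)) if np.isscalar(radii) else np.asarray(radii, float)
    if radii_arr.shape != (n,):
        raise ConfigError("radii must be scalar or one per center")
    if np.any(radii_arr <= 0) or probe <= 0:
        raise ConfigError("radii and probe must be positive")

    distinct = sorted(set(radii_arr.tolist()))
    if len(distinct) > len(_ELEMENT_POOL):
        raise ConfigError(f"at most {len(_ELEMENT_POOL)} distinct radii supported")
    element_of = {r: _ELEMENT_POOL[k] for k, r in enumerate(distinct)}
    radius_set = {el: r for r, el in element_of.items()}

    expanded = radii_arr + probe
    _pairwise_only_check(centers, expanded)

    # Closed-form ledger: additive cap subtraction over pairs.
    per_atom = []
    for i in range(n):
        area = 4.0 * math.pi * expanded[i] ** 2
        for j in range(n):
            if i == j:
                continue
            d = float(np.linalg.norm(centers[j] - centers[i]))
            h = _cap_height(expanded[i], expanded[j], d)
            area -= 2.0 * math.pi * expanded[i] * h
        per_atom.append(area)

    if chain_ids is None:
        chain_ids = ["X"] * n
    if len(chain_ids) != n:
        raise ConfigError("chain_ids must match the number of centers")
    chains: dict[str, list[Residue]] = {}
    for i, (c, r) in enumerate(zip(centers, radii_arr)):
        el = element_of[float(r)]
        atom = Atom(name=el, element=el, position=tuple(c), b_factor=0.0)
        chains.setdefault(chain_ids[i], []).append(
            Residue(seq_id=i + 1, name="UNK", atoms=[atom])
        )
    model = StructureModel(
        "sphere_cluster", [Chain(cid, res) for cid, res in chains.items()]
    )
    ledger = {
        "kind": "sphere_cluster",
        "probe_radius": probe,
        "radius_set": radius_set,
        "per_atom_area": per_atom,
        "total_area": float(sum(per_atom)),
        "chain_ids": list(chain_ids),
    }
    return model, ledger


# ---------------------------------------------------------------------------
# Mock TCR-pMHC complex


def _domain_chain(chain_id: str, centroid: np.ndarray, start_seq: int = 1,
                  spread: float = 1.5) -> Chain:
    """Five single-CA residues whose Calpha centroid is exactly ``centroid``."""
    offsets = spread * np.array(
        [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float
    )
    residues = [
        Residue(
            seq_id=start_seq + k,
            name="GLY",
            atoms=[Atom(name="CA", element="C", position=tuple(centroid + off))],
        )
        for k, off in enumerate(offsets)
    ]
    return Chain(chain_id, residues)


def make_mock_complex(
    crossing_angle: float = 57.49,
    incident_angle: float = 13.13,
    peptide_length: int = 9,
    tcr_height: float = 10.0,
    tcr_half_length: float = 10.0,
    contact_distance: float | None = 3.5,
) -> tuple[ComplexDefinition, dict]:
    """Idealised ternary complex with known docking angles and contacts.

    The pMHC platform lies in the z=0 plane: the peptide runs along +x
    through the origin and two pseudo-helices of the heavy chain flank
    it at y = +/-5. The TCR inter-domain axis is laid at the requested
    crossing angle (in-plane, relative to the peptide axis) and incident
    angle (out-of-plane tilt), with the V-domain centroids at
    ``tcr_height`` above the platform.

    If ``contact_distance`` is given, one probe atom is added to the
    TCR-alpha chain straight above the central peptide residue at that
    distance; the ledger lists the cross-interface atom pairs within
    4 A computed by direct brute force over the generated coordinates.
    """
    if not (0.0 <= crossing_angle < 180.0):
        raise ConfigError("crossing_angle must be in [0, 180)")
    if not (0.0 <= incident_angle <= 90.0):
        raise ConfigError("incident_angle must be in [0, 90]")
    chi = math.radians(crossing_angle)
    theta = math.radians(incident_angle)

    spacing = 3.5
    pep_atoms = [
        Residue(
            seq_id=i + 1, name="GLY",
            atoms=[Atom(name="CA", element="C",
                        position=(spacing * (i - (peptide_length - 1) / 2), 0.0, 0.0))],
        )
        for i in range(peptide_length)
    ]
    peptide = Chain("P", pep_atoms)

    heavy_res = []
    for seq in range(50, 87):
        heavy_res.append(
            Residue(seq_id=seq, name="GLY",
                    atoms=[Atom(name="CA", element="C",
                                position=(1.5 * (seq - 68), 8.0, 0.0))])
        )
    for seq in range(138, 177):
        heavy_res.append(
            Residue(seq_id=seq, name="GLY",
                    atoms=[Atom(name="CA", element="C",
                                position=(1.5 * (seq - 157), -8.0, 0.0))])
        )
    heavy = Chain("M", heavy_res)

    d_plane = np.array([math.cos(chi), math.sin(chi), 0.0])
    axis = math.cos(theta) * d_plane + math.sin(theta) * np.array([0.0, 0.0, 1.0])
    center = np.array([0.0, 0.0, tcr_height])
    p_alpha = center - tcr_half_length * axis
    p_beta = center + tcr_half_length * axis
    alpha = _domain_chain("A", p_alpha)
    beta = _domain_chain("B", p_beta)

    if contact_distance is not None:
        mid = pep_atoms[peptide_length // 2].atoms[0].xyz
        probe_pos = mid + np.array([0.0, 0.0, contact_distance])
        # seq_id above the V-domain window so the probe atom does not
        # perturb the domain centroid used for the TCR axis.
        alpha.residues.append(
            Residue(seq_id=150, name="GLY",
                    atoms=[Atom(name="CA", element="C", position=tuple(probe_pos))])
        )

    model = StructureModel("mock_complex", [heavy, peptide, alpha, beta])
    cx = ComplexDefinition(
        model=model,
        roles={
            "M": ChainRole.MHC_HEAVY,
            "P": ChainRole.PEPTIDE,
            "A": ChainRole.TCR_ALPHA,
            "B": ChainRole.TCR_BETA,
        },
    )

    # Ground-truth contacts by brute force over the generated coordinates.
    cutoff = 4.0
    tcr_atoms = [(c.chain_id, r.seq_id, a.name, a.xyz)
                 for c in (alpha, beta) for r in c.residues for a in r.atoms]
    pmhc_atoms = [(c.chain_id, r.seq_id, a.name, a.xyz)
                  for c in (heavy, peptide) for r in c.residues for a in r.atoms]
    true_contacts = []
    for ca, sa, na, xa in tcr_atoms:
        for cb, sb, nb, xb in pmhc_atoms:
            d = float(np.linalg.norm(xa - xb))
            if d <= cutoff:
                true_contacts.append(
                    {"tcr": [ca, sa, na], "pmhc": [cb, sb, nb], "distance": d}
                )
    ledger = {
        "kind": "mock_complex",
        "crossing_angle": crossing_angle,
        "incident_angle": incident_angle,
        "contact_cutoff": cutoff,
        "contacts": true_contacts,
    }
    return cx, ledger


# ---------------------------------------------------------------------------
# B-factor peptide


def make_bfactor_peptide(
    b_values: Sequence[Sequence[float]] | None = None,
    n_residues: int = 9,
    atoms_per_residue: int = 4,
    seed: int = 0,
    chain_id: str = "C",
) -> tuple[StructureModel, dict]:
    """Extended pseudo-peptide with planted per-atom B-factors.

    ``b_values`` gives per-residue lists of atom B-factors; omitted, they
    are drawn uniformly from [10, 60] with the given seed. The ledger
    records the planted values and the per-residue heavy-atom means
    (recomputed here with plain numpy, independently of the descriptors
    module).
    """
    if b_values is None:
        rng = np.random.default_rng(seed)
        b_values = rng.uniform(10.0, 60.0, size=(n_residues, atoms_per_residue)).tolist()
    names = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]
    residues = []
    for i, bs in enumerate(b_values):
        if not bs:
            raise ConfigError(f"residue {i + 1} has no B-factors")
        atoms = [
            Atom(
                name=names[k % len(names)],
                element=names[k % len(names)][0],
                position=(3.8 * i, 0.5 * (k % 2), 0.4 * k),
                b_factor=float(b),
            )
            for k, b in enumerate(bs)
        ]
        residues.append(Residue(seq_id=i + 1, name="ALA", atoms=atoms))
    model = StructureModel("bfactor_peptide", [Chain(chain_id, residues)])
    per_res_mean = [float(np.mean(bs)) for bs in b_values]
    ledger = {
        "kind": "bfactor_peptide",
        "b_values": [list(map(float, bs)) for bs in b_values],
        "per_residue_mean": per_res_mean,
    }
    return model, ledger


# ---------------------------------------------------------------------------
# Titrations


def make_titration(
    bottom: float = 0.0,
    top: float = 1.0,
    ec50: float = 1e-9,
    hill: float = 1.0,
    doses: Sequence[float] | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
) -> tuple[TitrationSeries, dict]:
    """Dose-response data from a known 4PL truth with Gaussian noise.

    Default doses: 10 half-log steps centred on the EC50, each measured
    in triplicate — the standard design of cell-based titration assays
    (triplicate wells per concentration). Deterministic under a fixed
    seed.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if doses is None:
        doses = ec50 * 10.0 ** np.arange(-2.25, 2.75, 0.5)
    doses = np.asarray(doses, dtype=float)
    d = np.repeat(doses, replicates)
    rng = np.random.default_rng(seed)
    r = four_pl(d, bottom, top, ec50, hill)
    if sigma > 0:
        r = r + rng.normal(0.0, sigma, size=r.shape)
    reps = tuple(int(i % replicates) for i in range(len(d)))
    series = TitrationSeries(doses=d, responses=r, replicate_ids=reps)
    truth = {
        "kind": "titration",
        "bottom": bottom, "top": top, "ec50": ec50, "hill": hill,
        "sigma": sigma, "seed": seed, "replicates": replicates,
    }
    return series, truth


def write_fixture(model: StructureModel, ledger: dict, path: str | Path) -> None:
    """Write a fixture as PDB plus a JSON ledger side-file (``.json``)."""
    from .structure_io import write_structure

    path = Path(path)
    write_structure(model, path, format="pdb")
    path.with_suffix(".json").write_text(json.dumps(ledger, indent=2))
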