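"""Detection and classification of inter-component non-covalent contacts.

All criteria are heavy-atom distance cutoffs, matching common
crystallographic interface-description practice:

* van der Waals contact: any heavy-atom pair across the interface within
  4.0 A (inclusive);
* hydrogen bond: N/O ... N/O pair within 3.5 A (no donor-acceptor angle
  term by default — an optional geometric filter can be layered on by the
  caller);
* salt bridge: Asp/Glu carboxylate oxygen to Lys/Arg/His side-chain
  nitrogen within 4.0 A; histidine is treated as chargeable. The salt
  bridge label supersedes the hydrogen-bond label for the same pair;
* water bridge: a water oxygen within the hydrogen-bond cutoff of at
  least one polar atom on each side links every qualifying pair.

Neighbour search uses a k-d tree; the result set is identical to the
all-pairs brute force (a tested invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError
from .model import ChainRole, ComplexDefinition, StructureModel
from .sasa import polymer_subset

__all__ = [
    "AtomRef",
    "ContactKind",
    "Contact",
    "WaterBridge",
    "find_contacts",
    "classify_polar",
    "find_water_bridges",
    "HBOND_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
    "VDW_CUTOFF",
]

VDW_CUTOFF = 4.0
HBOND_CUTOFF = 3.5
SALT_BRIDGE_CUTOFF = 4.0

#: Side-chain atoms of formally charged groups.
_ACIDIC_OXYGENS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_BASIC_NITROGENS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}


class AtomRef(NamedTuple):
    """Hashable reference to one atom in a complex."""

    chain_id: str
    seq_id: int
    icode: str
    res_name: str
    atom_name: str
    element: str

    @property
    def is_polar(self) -> bool:
        return self.element.upper() in ("N", "O")

    @property
    def is_acidic_oxygen(self) -> bool:
        return self.atom_name in _ACIDIC_OXYGENS.get(self.res_name, ())

    @property
    def is_basic_nitrogen(self) -> bool:
        return self.atom_name in _BASIC_NITROGENS.get(self.res_name, ())

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_id}{self.icode}/{self.atom_name}"


class ContactKind(str, Enum):
    VDW = "vdw"
    HBOND = "hbond"
    SALT_BRIDGE = "salt_bridge"


@dataclass(frozen=True)
class Contact:
    """One inter-side heavy-atom contact."""

    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    kind: ContactKind = ContactKind.VDW

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError(f"non-positive contact distance {self.distance}")

    def swapped(self) -> "Contact":
        return Contact(self.atom_b, self.atom_a, self.distance, self.kind)


@dataclass(frozen=True)
class WaterBridge:
    """A water molecule hydrogen-bonded to polar atoms on both sides."""

    water: AtomRef
    partner_a: AtomRef
    partner_b: AtomRef
    d_a: float
    d_b: float


def _side_atoms(cx: ComplexDefinition, roles: Iterable[ChainRole | str]):
    model = polymer_subset(cx, roles=roles)
    refs: list[AtomRef] = []
    coords: list[tuple[float, float, float]] = []
    for chain, res, atom in model.iter_atoms():
        refs.append(
            AtomRef(chain.chain_id, res.seq_id, res.icode, res.name,
                    atom.name, atom.element)
        )
        coords.append(atom.position)
    return refs, np.asarray(coords, dtype=float)


def find_contacts(
    cx: ComplexDefinition,
    side_a: Iterable[ChainRole | str],
    side_b: Iterable[ChainRole | str],
    cutoff: float = VDW_CUTOFF,
) -> list[Contact]:
    """All heavy-atom pairs across the two sides within ``cutoff`` A.

    Sides are named by chain roles and must be disjoint and non-empty.
    The boundary is inclusive. Contacts come back sorted by
    (chain, residue, atom) of side A, then distance.
    """
    roles_a = {ChainRole(r) for r in side_a}
    roles_b = {ChainRole(r) for r in side_b}
    if roles_a & roles_b:
        raise ConfigError(f"overlapping sides: {sorted(r.value for r in roles_a & roles_b)}")
    if cutoff <= 0:
        raise ConfigError(f"cutoff must be > 0, got {cutoff}")
    refs_a, xyz_a = _side_atoms(cx, roles_a)
    refs_b, xyz_b = _side_atoms(cx, roles_b)

    tree_a = cKDTree(xyz_a)
    tree_b = cKDTree(xyz_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    contacts: list[Contact] = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            contacts.append(Contact(refs_a[i], refs_b[j], d))
    contacts.sort(key=lambda c: (c.atom_a, c.atom_b))
    return contacts


def classify_polar(contacts: Sequence[Contact]) -> list[Contact]:
    """Re-label contacts as hydrogen bonds / salt bridges where warranted.

    Pure reclassification: the contact set is unchanged, only ``kind``
    may change. Salt bridge supersedes hydrogen bond.
    """
    out: list[Contact] = []
    for c in contacts:
        kind = ContactKind.VDW
        a, b = c.atom_a, c.atom_b
        salt_pair = (
            (a.is_acidic_oxygen and b.is_basic_nitrogen)
            or (b.is_acidic_oxygen and a.is_basic_nitrogen)
        )
        if salt_pair and c.distance <= SALT_BRIDGE_CUTOFF:
            kind = ContactKind.SALT_BRIDGE
        elif a.is_polar and b.is_polar and c.distance <= HBOND_CUTOFF:
            kind = ContactKind.HBOND
        out.append(replace(c, kind=kind))
    return out


def find_water_bridges(
    cx: ComplexDefinition,
    side_a: Iterable[ChainRole | str],
    side_b: Iterable[ChainRole | str],
    cutoff: float = HBOND_CUTOFF,
) -> list[WaterBridge]:
    """Waters linking polar atoms on both sides within ``cutoff`` A.

    Every water whose oxygen lies within the cutoff of at least one
    polar (N/O) atom on each side yields one bridge per qualifying
    (partner_a, partner_b) pair. No waters in the complex -> empty list.
    """
    waters: list[tuple[AtomRef, np.ndarray]] = []
    for chain in cx.chains_with_role(ChainRole.WATER):
        for res in chain.residues:
            for atom in res.atoms:
                if atom.element.upper() == "O":
                    waters.append(
                        (AtomRef(chain.chain_id, res.seq_id, res.icode,
                                 res.name, atom.name, atom.element), atom.xyz)
                    )
    # Waters may also sit in polymer chains of mixed content.
    for chain in cx.model.chains:
        if cx.roles[chain.chain_id] == ChainRole.WATER:
            continue
        for res in chain.residues:
            if res.is_water:
                for atom in res.atoms:
                    if atom.element.upper() == "O":
                        waters.append(
                            (AtomRef(chain.chain_id, res.seq_id, res.icode,
                                     res.name, atom.name, atom.element), atom.xyz)
                        )
    if not waters:
        return []

    def polar_side(roles):
        refs, xyz = _side_atoms(cx, roles)
        if not refs:
            return [], xyz.reshape(0, 3)
        mask = np.array([r.is_polar for r in refs], dtype=bool)
        return [r for r, m in zip(refs, mask) if m], xyz[mask]

    refs_a, xyz_a = polar_side(side_a)
    refs_b, xyz_b = polar_side(side_b)
    if not refs_a or not refs_b:
        return []
    tree_a = cKDTree(xyz_a)
    tree_b = cKDTree(xyz_b)

    bridges: list[WaterBridge] = []
    for wref, wxyz in waters:
        near_a = tree_a.query_ball_point(wxyz, cutoff)
        near_b = tree_b.query_ball_point(wxyz, cutoff)
        for i in near_a:
            for j in near_b:
                bridges.append(
                    WaterBridge(
                        water=wref,
                        partner_a=refs_a[i],
                        partner_b=refs_b[j],
                        d_a=float(np.linalg.norm(wxyz - xyz_a[i])),
                        d_b=float(np.linalg.norm(wxyz - xyz_b[j])),
                    )
                )
    bridges.sort(key=lambda b: (b.water, b.partner_a, b.partner_b))
    return bridges
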