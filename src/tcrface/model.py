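"""Hierarchical coordinate model for macromolecular structures.

The model mirrors the PDB hierarchy (structure > chain > residue > atom)
with author numbering kept verbatim. Coordinates are in Angstrom,
B-factors (Debye-Waller factors) in Angstrom^2. Hydrogens are dropped at
parse time because every distance cutoff used downstream is a heavy-atom
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ChainRole",
    "ComplexDefinition",
    "STANDARD_AMINO_ACIDS",
]

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


def three_to_one(name: str) -> str:
    """One-letter code for a standard residue name, ``X`` otherwise."""
    return _THREE_TO_ONE.get(name.upper(), "X")


def one_to_three(code: str) -> str:
    try:
        return _ONE_TO_THREE[code.upper()]
    except KeyError:
        raise ValueError(f"not a standard one-letter amino-acid code: {code!r}")


@dataclass(frozen=True)
class Atom:
    """A heavy atom with coordinates and crystallographic metadata."""

    name: str
    element: str
    position: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy outside [0,1]: {self.occupancy}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor: {self.b_factor}")
        if not self.element:
            raise ValueError(f"atom {self.name!r} has an empty element symbol")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    """One residue; ``(seq_id, icode)`` is unique within its chain."""

    seq_id: int
    name: str
    atoms: list[Atom]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.seq_id} has no atoms")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.name} {self.seq_id}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq_id}{self.icode}"

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_id: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id and r.icode == icode:
                return r
        raise KeyError(f"residue {seq_id}{icode} not found in chain {self.chain_id}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def n_standard_residues(self) -> int:
        return sum(1 for r in self.residues if r.is_standard)

    def sequence(self) -> str:
        return "".join(three_to_one(r.name) for r in self.residues if r.is_standard)


@dataclass
class StructureModel:
    """A parsed structure: unique-id chains holding residues holding atoms."""

    identifier: str
    chains: list[Chain]
    resolution: float | None = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.identifier}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not found in {self.identifier}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def coords(self) -> np.ndarray:
        """All atom coordinates, file order, shape (n_atoms, 3)."""
        out = np.empty((self.n_atoms, 3), dtype=float)
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            out[i] = a.position
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    replace(a, position=tuple(R @ a.xyz + t)) for a in r.atoms
                ]
                residues.append(Residue(r.seq_id, r.name, atoms, r.icode))
            chains.append(Chain(c.chain_id, residues))
        return StructureModel(self.identifier, chains, self.resolution)


class ChainRole(str, Enum):
    """Biological role of a chain inside a (p)MHC / TCR complex."""

    MHC_HEAVY = "mhc_heavy"
    B2M = "b2m"
    PEPTIDE = "peptide"
    TCR_ALPHA = "tcr_alpha"
    TCR_BETA = "tcr_beta"
    WATER = "water"
    HETERO = "hetero"
    OTHER = "other"


#: Roles that take part in surface / interface computations by default.
POLYMER_ROLES = frozenset(
    {ChainRole.MHC_HEAVY, ChainRole.B2M, ChainRole.PEPTIDE,
     ChainRole.TCR_ALPHA, ChainRole.TCR_BETA, ChainRole.OTHER}
)


@dataclass
class ComplexDefinition:
    """A structure plus a complete chain-id -> role assignment."""

    model: StructureModel
    roles: dict[str, ChainRole]

    def __post_init__(self) -> None:
        missing = set(self.model.chain_ids) - set(self.roles)
        extra = set(self.roles) - set(self.model.chain_ids)
        if missing:
            raise ValueError(f"chains without a role: {sorted(missing)}")
        if extra:
            raise ValueError(f"roles for unknown chains: {sorted(extra)}")
        for cid, role in self.roles.items():
            if role == ChainRole.PEPTIDE and len(self.model.chain(cid)) > 15:
                raise ValueError(
                    f"chain {cid} assigned role peptide but has "
                    f"{len(self.model.chain(cid))} residues (> 15)"
                )

    def chains_with_role(self, role: ChainRole | str) -> list[Chain]:
        role = ChainRole(role)
        return [c for c in self.model.chains if self.roles[c.chain_id] == role]

    def chain_ids_with_roles(self, roles: Iterable[ChainRole | str]) -> list[str]:
        wanted = {ChainRole(r) for r in roles}
        return [cid for cid in self.model.chain_ids if self.roles[cid] in wanted]

    @property
    def peptide(self) -> Chain:
        chains = self.chains_with_role(ChainRole.PEPTIDE)
        if len(chains) != 1:
            raise ValueError(f"expected exactly one peptide chain, got {len(chains)}")
        return chains[0]

    def peptide_position(self, ordinal: int) -> Residue:
        """Peptide residue by 1-based ordinal (p1 .. pN), not author seq_id."""
        pep = self.peptide
        if not (1 <= ordinal <= len(pep)):
            raise IndexError(f"peptide position p{ordinal} out of range 1..{len(pep)}")
        return pep.residues[ordinal - 1]
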