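"""Partitioning the TCR-pMHC interface by chain, CDR loop and target.

Buried area is attributed on each side of the interface separately:
per-loop shares are computed from the TCR-side per-residue BSA (a TCR
atom cannot be attributed to a single partner), while the MHC-vs-peptide
split is computed on the pMHC side, where each buried atom belongs to
exactly one of the two targets — the only reading under which the two
target percentages sum to 100 by construction. Contact counts are
reported alongside as a cross-check.

CDR loop definitions are configuration: IMGT-numbered defaults are
shipped (CDR1 27-38, CDR2 56-65, CDR3 105-117) but deposited structures
keep author numbering, so ranges should normally be supplied per chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contacts import Contact, find_contacts
from .errors import ConfigError, PairingError
from .model import ChainRole, ComplexDefinition, StructureModel
from .sasa import (
    ResidueKey,
    SASAParams,
    compute_sasa,
    polymer_subset,
)

__all__ = [
    "CDRAnnotation",
    "DEFAULT_IMGT_RANGES",
    "annotate_cdrs",
    "InterfacePartition",
    "partition_interface",
    "sasa_delta_per_residue",
]

TCR_ROLES = (ChainRole.TCR_ALPHA, ChainRole.TCR_BETA)
PMHC_ROLES = (ChainRole.MHC_HEAVY, ChainRole.B2M, ChainRole.PEPTIDE)

#: IMGT-numbering CDR ranges, identical for alpha and beta chains.
DEFAULT_IMGT_RANGES: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}

_LOOP_SUFFIX = {ChainRole.TCR_ALPHA: "a", ChainRole.TCR_BETA: "b"}


@dataclass(frozen=True)
class CDRAnnotation:
    """Residue-range definition of the six CDR loops.

    ``ranges`` maps a TCR chain role to ``{loop_base: (lo, hi)}`` in the
    chain's author numbering; anything not covered is framework. Loop
    labels are suffixed a/b by chain (CDR1a .. CDR3b).
    """

    ranges: Mapping[ChainRole, Mapping[str, tuple[int, int]]]

    def loop_of(self, role: ChainRole, seq_id: int) -> str:
        for base, (lo, hi) in self.ranges.get(role, {}).items():
            if lo <= seq_id <= hi:
                return f"{base}{_LOOP_SUFFIX[role]}"
        return "framework"

    @property
    def loop_names(self) -> list[str]:
        names = []
        for role in TCR_ROLES:
            for base in self.ranges.get(role, {}):
                names.append(f"{base}{_LOOP_SUFFIX[role]}")
        return names


def annotate_cdrs(
    cx: ComplexDefinition,
    ranges: Mapping[str, Mapping[str, Sequence[int]]] | None = None,
) -> CDRAnnotation:
    """Build a validated CDR annotation for the complex's TCR chains.

    ``ranges`` maps ``"tcr_alpha"``/``"tcr_beta"`` to ``{loop: (lo, hi)}``
    in author numbering. With no argument the IMGT defaults are applied
    to both chains. Overlapping loops on a chain raise
    :class:`ConfigError`; an empty mapping labels everything framework
    and warns.
    """
    if ranges is None:
        ranges = {
            "tcr_alpha": dict(DEFAULT_IMGT_RANGES),
            "tcr_beta": dict(DEFAULT_IMGT_RANGES),
        }
    norm: dict[ChainRole, dict[str, tuple[int, int]]] = {}
    for role_name, loops in ranges.items():
        role = ChainRole(role_name)
        if role not in TCR_ROLES:
            raise ConfigError(f"CDR ranges given for non-TCR role {role_name!r}")
        norm[role] = {}
        for loop, rng in loops.items():
            lo, hi = int(rng[0]), int(rng[1])
            if lo > hi:
                raise ConfigError(f"{role_name}.{loop}: bad range {lo}-{hi}")
            norm[role][loop] = (lo, hi)
        spans = sorted(norm[role].values())
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ConfigError(
                    f"overlapping CDR ranges on {role_name}: "
                    f"{lo1}-{hi1} and {lo2}-{hi2}"
                )
    if not any(norm.get(role) for role in TCR_ROLES):
        warnings.warn("empty CDR ranges: all TCR residues labelled framework")
    return CDRAnnotation(ranges=norm)


@dataclass
class InterfacePartition:
    """Interface shares by CDR loop and by pMHC-side target."""

    per_loop: dict[str, dict[str, float]]  # loop -> bsa, bsa_pct, contacts, contact_pct
    tcr_side_bsa: float
    mhc_bsa: float
    peptide_bsa: float
    mhc_contacts: int
    peptide_contacts: int

    @property
    def target_split(self) -> dict[str, float]:
        """pMHC-side buried area split, % against MHC heavy chain vs peptide."""
        total = self.mhc_bsa + self.peptide_bsa
        if total <= 0:
            return {"mhc_pct": 0.0, "peptide_pct": 0.0}
        return {
            "mhc_pct": 100.0 * self.mhc_bsa / total,
            "peptide_pct": 100.0 * self.peptide_bsa / total,
        }

    @property
    def contact_split(self) -> dict[str, float]:
        total = self.mhc_contacts + self.peptide_contacts
        if total == 0:
            return {"mhc_pct": 0.0, "peptide_pct": 0.0}
        return {
            "mhc_pct": 100.0 * self.mhc_contacts / total,
            "peptide_pct": 100.0 * self.peptide_contacts / total,
        }


def _per_residue_bsa(
    cx: ComplexDefinition,
    side_roles,
    other_roles,
    params: SASAParams,
) -> dict[ResidueKey, float]:
    """BSA of each residue on ``side_roles`` against ``other_roles``."""
    side = polymer_subset(cx, roles=side_roles)
    other = polymer_subset(cx, roles=other_roles)
    both = StructureModel(
        cx.model.identifier, list(side.chains) + list(other.chains)
    )
    free = compute_sasa(side, params).per_residue
    bound = compute_sasa(both, params).per_residue
    return {key: area - bound.get(key, 0.0) for key, area in free.items()}


def partition_interface(
    cx: ComplexDefinition,
    annotation: CDRAnnotation | None = None,
    params: SASAParams | None = None,
    contact_cutoff: float = 4.0,
) -> InterfacePartition:
    """Split the TCR-pMHC interface by CDR loop and by target.

    Requires a ternary complex (both TCR chains, MHC heavy chain and
    peptide). Loop shares use the TCR-side per-residue BSA; the
    MHC-vs-peptide split uses pMHC-side per-chain BSA. Contact counts
    (heavy-atom pairs within ``contact_cutoff``) are grouped the same
    way.
    """
    params = params or SASAParams()
    annotation = annotation or annotate_cdrs(cx)
    for role in (*TCR_ROLES, ChainRole.MHC_HEAVY, ChainRole.PEPTIDE):
        if not cx.chains_with_role(role):
            raise ConfigError(f"interface partition requires a {role.value} chain")

    pmhc_present = [r for r in PMHC_ROLES if cx.chains_with_role(r)]
    tcr_bsa = _per_residue_bsa(cx, TCR_ROLES, pmhc_present, params)
    pmhc_bsa = _per_residue_bsa(cx, pmhc_present, TCR_ROLES, params)

    role_of_chain = {cid: cx.roles[cid] for cid in cx.model.chain_ids}

    per_loop: dict[str, dict[str, float]] = {}
    for loop in [*annotation.loop_names, "framework"]:
        per_loop[loop] = {"bsa": 0.0, "bsa_pct": 0.0, "contacts": 0, "contact_pct": 0.0}
    for key, bsa in tcr_bsa.items():
        if bsa <= 0:
            continue
        loop = annotation.loop_of(role_of_chain[key.chain_id], key.seq_id)
        per_loop[loop]["bsa"] += bsa

    contacts = find_contacts(cx, TCR_ROLES, pmhc_present, cutoff=contact_cutoff)
    mhc_contacts = peptide_contacts = 0
    for c in contacts:
        loop = annotation.loop_of(role_of_chain[c.atom_a.chain_id], c.atom_a.seq_id)
        per_loop[loop]["contacts"] += 1
        target = role_of_chain[c.atom_b.chain_id]
        if target == ChainRole.PEPTIDE:
            peptide_contacts += 1
        elif target == ChainRole.MHC_HEAVY:
            mhc_contacts += 1

    total_bsa = sum(v["bsa"] for v in per_loop.values())
    total_contacts = sum(v["contacts"] for v in per_loop.values())
    for v in per_loop.values():
        v["bsa_pct"] = 100.0 * v["bsa"] / total_bsa if total_bsa > 0 else 0.0
        v["contact_pct"] = (
            100.0 * v["contacts"] / total_contacts if total_contacts else 0.0
        )

    mhc_bsa = sum(
        b for k, b in pmhc_bsa.items()
        if b > 0 and role_of_chain[k.chain_id] == ChainRole.MHC_HEAVY
    )
    pep_bsa = sum(
        b for k, b in pmhc_bsa.items()
        if b > 0 and role_of_chain[k.chain_id] == ChainRole.PEPTIDE
    )
    return InterfacePartition(
        per_loop=per_loop,
        tcr_side_bsa=float(total_bsa),
        mhc_bsa=float(mhc_bsa),
        peptide_bsa=float(pep_bsa),
        mhc_contacts=mhc_contacts,
        peptide_contacts=peptide_contacts,
    )


def sasa_delta_per_residue(
    unbound: ComplexDefinition,
    bound: ComplexDefinition,
    chain_map: Mapping[str, str],
    params: SASAParams | None = None,
) -> tuple[list[dict], list[str]]:
    """Per-residue SASA(unbound) - SASA(bound complex).

    ``chain_map`` pairs unbound chain ids to bound chain ids; residues
    pair by ordinal and must agree on residue name — mismatches are
    reported in the second return value, never silently dropped.
    Positive deltas mark residues buried by the new partner.
    """
    params = params or SASAParams()
    if not chain_map:
        raise PairingError("empty chain_map")
    for cu, cb in chain_map.items():
        if cu not in unbound.model.chain_ids:
            raise PairingError(f"chain {cu!r} not in unbound structure")
        if cb not in bound.model.chain_ids:
            raise PairingError(f"chain {cb!r} not in bound structure")

    sasa_unbound = compute_sasa(polymer_subset(unbound), params).per_residue
    sasa_bound = compute_sasa(polymer_subset(bound), params).per_residue

    rows: list[dict] = []
    problems: list[str] = []
    for cu, cb in chain_map.items():
        chain_u = unbound.model.chain(cu)
        chain_b = bound.model.chain(cb)
        n = min(len(chain_u), len(chain_b))
        if len(chain_u) != len(chain_b):
            problems.append(
                f"chain {cu}->{cb}: residue counts differ "
                f"({len(chain_u)} vs {len(chain_b)}); comparing first {n}"
            )
        for ru, rb in zip(chain_u.residues[:n], chain_b.residues[:n]):
            if ru.name != rb.name:
                problems.append(
                    f"chain {cu}->{cb}: residue name mismatch {ru.label} vs {rb.label}"
                )
                continue
            a_u = sasa_unbound.get(ResidueKey(cu, ru.seq_id, ru.icode), 0.0)
            a_b = sasa_bound.get(ResidueKey(cb, rb.seq_id, rb.icode), 0.0)
            rows.append(
                {
                    "chain": cu,
                    "seq_id": ru.seq_id,
                    "name": ru.name,
                    "sasa_unbound": a_u,
                    "sasa_bound": a_b,
                    "delta": a_u - a_b,
                }
            )
    return rows, problems
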