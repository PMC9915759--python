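"""Peptide-level descriptors: B-factor segment statistics, positional-
scanning libraries, and the neoantigen class assignment.

Neoantigen classes follow the anchor-based definition used for MHC-I
epitopes: a mutation whose side chain is solvent-facing and can touch
the TCR directly is *class I*; a mutation buried as an MHC anchor, which
acts on the TCR only indirectly through peptide presentation and
conformation, is *class II*. Anchor positions are inputs (for H2-Db:
position 5 and the C-terminal residue) — the package never predicts
anchors from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import SelectionError, ValidationError
from .model import Chain, Residue, StructureModel, one_to_three

__all__ = [
    "SegmentStats",
    "bfactor_segment_stats",
    "PositionalScanLibrary",
    "ScanVariant",
    "positional_scan",
    "NeoAgClass",
    "classify_neoantigen",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# B-factor (Debye-Waller factor) segment statistics


@dataclass(frozen=True)
class SegmentStats:
    """Mean +/- SD (A^2) of per-residue heavy-atom mean B over a segment."""

    label: str
    mean: float
    sd: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("negative SD")
        if self.n_residues < 1:
            raise ValueError("empty segment")


def _residue_mean_b(res: Residue) -> float:
    return float(np.mean([a.b_factor for a in res.atoms]))


def bfactor_segment_stats(
    chain: Chain,
    segments: Sequence[tuple[str, Iterable[int]]],
    ddof: int = 1,
) -> list[SegmentStats]:
    """Per-segment flexibility statistics for a chain.

    Each residue contributes its heavy-atom mean B; each segment reports
    mean and SD across those residue means. ``segments`` pairs a label
    with 1-based residue ordinals within the chain (``[1, 2, 3, 4]`` for
    peptide positions p1-p4). ``ddof=1`` gives the sample SD (default);
    ``ddof=0`` the population SD.
    """
    stats: list[SegmentStats] = []
    for label, ordinals in segments:
        ordinals = list(ordinals)
        if not ordinals:
            raise SelectionError(f"segment {label!r} is empty")
        values = []
        for k in ordinals:
            if not (1 <= k <= len(chain)):
                raise SelectionError(
                    f"segment {label!r}: ordinal {k} outside chain of {len(chain)}"
                )
            values.append(_residue_mean_b(chain.residues[k - 1]))
        arr = np.asarray(values)
        sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        stats.append(SegmentStats(label, float(arr.mean()), sd, len(arr)))
    return stats


# ---------------------------------------------------------------------------
# Positional-scanning library


@dataclass(frozen=True)
class ScanVariant:
    position: int  # 1-based
    substitution: str  # one-letter code
    sequence: str

    @property
    def variant_id(self) -> str:
        return f"p{self.position}{self.substitution}"


@dataclass(frozen=True)
class PositionalScanLibrary:
    """Exhaustive single-substitution variants of a parent peptide."""

    parent: str
    variants: tuple[ScanVariant, ...]

    def at_position(self, position: int) -> list[ScanVariant]:
        return [v for v in self.variants if v.position == position]

    def to_fasta(self) -> str:
        return "".join(f">{v.variant_id}\n{v.sequence}\n" for v in self.variants)


def positional_scan(peptide: str) -> PositionalScanLibrary:
    """Replace every position with each of the other 19 amino acids.

    Deterministic order: position-major, substitutions alphabetical.
    A length-L peptide yields exactly 19*L variants, none equal to the
    parent and all mutually distinct.
    """
    peptide = peptide.strip().upper()
    if not peptide:
        raise ValidationError("empty peptide sequence")
    bad = sorted(set(peptide) - set(AMINO_ACIDS))
    if bad:
        raise ValidationError(f"non-standard residue letters in {peptide!r}: {bad}")
    variants = []
    for i, native in enumerate(peptide):
        for sub in AMINO_ACIDS:
            if sub == native:
                continue
            variants.append(
                ScanVariant(i + 1, sub, peptide[:i] + sub + peptide[i + 1:])
            )
    return PositionalScanLibrary(parent=peptide, variants=tuple(variants))


# ---------------------------------------------------------------------------
# Neoantigen classification


@dataclass(frozen=True)
class NeoAgClass:
    """Anchor-based neoantigen class of a point-mutated epitope."""

    label: str  # class_I_solvent_exposed | class_II_anchor_buried
    mutated_position: int
    anchor_positions: tuple[int, ...]

    @property
    def is_anchor_mutation(self) -> bool:
        return self.label == "class_II_anchor_buried"


def classify_neoantigen(
    peptide: str,
    mutated_position: int,
    anchor_positions: Iterable[int],
) -> NeoAgClass:
    """Classify a neoepitope by where its mutation sits.

    ``anchor_positions`` are 1-based; negative values count from the
    C-terminus (-1 = last). For H2-Db-restricted 9-mers the canonical
    anchors are {5, 9}.
    """
    peptide = peptide.strip().upper()
    n = len(peptide)
    if not (1 <= mutated_position <= n):
        raise ValidationError(
            f"mutated position {mutated_position} outside 1..{n}"
        )
    anchors = []
    for a in anchor_positions:
        a = int(a)
        if a < 0:
            a = n + 1 + a
        if not (1 <= a <= n):
            raise ValidationError(f"anchor position {a} outside 1..{n}")
        anchors.append(a)
    anchors = tuple(sorted(set(anchors)))
    label = (
        "class_II_anchor_buried"
        if mutated_position in anchors
        else "class_I_solvent_exposed"
    )
    return NeoAgClass(label, mutated_position, anchors)
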