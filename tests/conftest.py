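"""Shared builders for synthetic test structures."""

from __future__ import annotations

import numpy as np
import pytest

from tcrface.model import (
    Atom,
    Chain,
    ChainRole,
    ComplexDefinition,
    Residue,
    StructureModel,
)


def gly_chain(chain_id: str, n: int, start_seq: int = 1,
              origin=(0.0, 0.0, 0.0), step=(3.8, 0.0, 0.0),
              b_factor: float = 20.0) -> Chain:
    """CA-only poly-glycine chain laid out on a line."""
    origin = np.asarray(origin, float)
    step = np.asarray(step, float)
    residues = [
        Residue(
            seq_id=start_seq + i,
            name="GLY",
            atoms=[Atom(name="CA", element="C",
                        position=tuple(origin + i * step), b_factor=b_factor)],
        )
        for i in range(n)
    ]
    return Chain(chain_id, residues)


def atoms_chain(chain_id: str, spec) -> Chain:
    """Chain from a list of (seq_id, res_name, atom_name, element, xyz)."""
    by_res: dict[int, tuple[str, list[Atom]]] = {}
    for seq_id, res_name, atom_name, element, xyz in spec:
        by_res.setdefault(seq_id, (res_name, []))[1].append(
            Atom(name=atom_name, element=element, position=tuple(xyz))
        )
    residues = [
        Residue(seq_id=s, name=nm, atoms=ats)
        for s, (nm, ats) in sorted(by_res.items())
    ]
    return Chain(chain_id, residues)


def two_sided_cx(side_a_spec, side_b_spec) -> ComplexDefinition:
    """Minimal complex with chain T (tcr_alpha) vs chain M (mhc_heavy)."""
    model = StructureModel(
        "pair", [atoms_chain("T", side_a_spec), atoms_chain("M", side_b_spec)]
    )
    return ComplexDefinition(
        model=model,
        roles={"T": ChainRole.TCR_ALPHA, "M": ChainRole.MHC_HEAVY},
    )


@pytest.fixture
def pmhc_like() -> ComplexDefinition:
    """Binary-complex stand-in: a 275-residue 'heavy chain', 99-residue
    'b2m' and a 9-residue peptide, all CA-only (synthetic, no real fold)."""
    heavy = gly_chain("H", 275, origin=(0, 0, 0), b_factor=30.0)
    b2m = gly_chain("B", 99, origin=(0, 30, 0), b_factor=30.0)
    pep = gly_chain("P", 9, origin=(0, 0, 5), step=(3.5, 0, 0), b_factor=40.0)
    model = StructureModel("pmhc_like", [heavy, b2m, pep])
    return ComplexDefinition(
        model=model,
        roles={"H": ChainRole.MHC_HEAVY, "B": ChainRole.B2M,
               "P": ChainRole.PEPTIDE},
    )


MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1      10.000  20.000  30.000  1.00 15.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.804   6.900  -5.500  0.60 10.00           C
ATOM      3  CA BALA A   1      11.904   7.000  -5.600  0.40 10.00           C
ATOM      4  CB AALA A   1      12.000   8.000  -6.000  0.50 10.00           C
ATOM      5  CB BALA A   1      12.100   8.100  -6.100  0.50 10.00           C
ATOM      6  H   ALA A   1      11.104   6.134  -6.504  1.00 10.00           H
ATOM      7  N   GLY A   2      14.000   6.000  -6.000  1.00 12.00           N
HETATM    8  O   HOH W 101      15.000   6.000  -6.000  1.00 20.00           O
END
"""
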