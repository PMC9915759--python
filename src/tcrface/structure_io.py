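"""Reading, writing and selecting macromolecular structures.

PDB and mmCIF parsing/writing is delegated to gemmi; this module maps the
gemmi hierarchy onto the package's :class:`~tcrface.model.StructureModel`,
applying the parse-time policy used throughout:

* hydrogens (and deuterium) are dropped — every cutoff downstream is a
  heavy-atom distance;
* for alternate-location groups only the highest-occupancy conformer is
  kept, ties broken by the alphabetically first altloc letter;
* author chain ids and author residue numbering are kept verbatim.
"""

from __future__ import annotations

import io
import os
import re
from pathlib import Path
from typing import Mapping

import gemmi

from .errors import (
    FormatError,
    ParseError,
    RoleAssignmentError,
    SelectionError,
)
from .model import (
    Atom,
    Chain,
    ChainRole,
    ComplexDefinition,
    Residue,
    StructureModel,
)

__all__ = [
    "parse_structure",
    "write_structure",
    "assign_roles",
    "select",
    "read_complex_config",
]

_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE", "CD",
}


def _infer_element(atom_name: str) -> str:
    """Best-effort element from a PDB atom name when the file omits it."""
    stripped = re.sub(r"[\d'\"]", "", atom_name).strip()
    if not stripped:
        raise ParseError(f"cannot infer element for atom name {atom_name!r}")
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) > 3:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _looks_like_cif(text: str) -> bool:
    head = text[:4000]
    return head.lstrip().startswith("data_") or "_atom_site." in head


def _read_gemmi(source: str | Path, fmt: str) -> gemmi.Structure:
    fmt = fmt.lower()
    if fmt not in ("pdb", "mmcif", "cif", "auto"):
        raise FormatError(f"unknown structure format {fmt!r}")

    is_path = isinstance(source, Path) or (
        isinstance(source, (str, os.PathLike))
        and "\n" not in str(source)
        and os.path.exists(source)
    )
    try:
        if is_path:
            path = str(source)
            if fmt == "auto":
                st = gemmi.read_structure(path)
            elif fmt == "pdb":
                st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
            else:
                st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            text = str(source)
            if "\n" not in text and not text.lstrip().startswith(("ATOM", "HETATM", "data_", "HEADER")):
                raise ParseError(f"structure source not found: {text!r}")
            if fmt == "auto":
                fmt = "mmcif" if _looks_like_cif(text) else "pdb"
            if fmt == "pdb":
                st = gemmi.read_pdb_string(text)
            else:
                doc = gemmi.cif.read_string(text)
                st = gemmi.make_structure_from_block(doc.sole_block())
    except ParseError:
        raise
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse structure: {exc}") from exc
    if len(st) == 0:
        raise ParseError("structure contains no models")
    return st


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per altloc group (highest occupancy, then first
    altloc letter); preserve file order of the surviving atoms."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        key = a.name
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _neg_altloc(a.altloc)) > (b.occupancy, _neg_altloc(b.altloc)):
                best[key] = a
    return [best[k] for k in order]


def _neg_altloc(altloc: str) -> int:
    # Higher is better: no altloc beats any letter; 'A' beats 'B'.
    return -ord(altloc) if altloc else 0


def parse_structure(source: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF structure into a :class:`StructureModel`.

    Parameters
    ----------
    source:
        Path to a structure file, or the file content as text.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension/content).

    Only the first model of multi-model files is read. Hydrogens are
    dropped and altloc groups collapsed to a single conformer.
    """
    st = _read_gemmi(source, format)
    gmodel = st[0]
    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            atoms: list[Atom] = []
            for ga in gres:
                elem = "H" if ga.element.is_hydrogen else ga.element.name
                if elem in ("H", "D"):
                    continue
                if elem in ("", "X"):
                    elem = _infer_element(ga.name)
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=elem,
                        position=(ga.pos.x, ga.pos.y, ga.pos.z),
                        b_factor=max(ga.b_iso, 0.0),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        is_hetero=(gres.het_flag == "H"),
                    )
                )
            if not atoms:
                continue
            atoms = _resolve_altlocs(atoms)
            residues.append(
                Residue(
                    seq_id=gres.seqid.num,
                    name=gres.name,
                    atoms=atoms,
                    icode=gres.seqid.icode.strip(),
                )
            )
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise ParseError("structure contains no heavy atoms")
    resolution = st.resolution if st.resolution > 0 else None
    name = st.name or (Path(source).stem if isinstance(source, (Path, os.PathLike)) else "structure")
    return StructureModel(identifier=str(name), chains=chains, resolution=resolution)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "H" if res.atoms[0].is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (format from extension when auto)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if fmt == "pdb":
        path.write_text(st.make_pdb_string())
    elif fmt in ("mmcif", "cif"):
        path.write_text(st.make_mmcif_document().as_string())
    else:
        raise FormatError(f"unknown structure format {format!r}")


# ---------------------------------------------------------------------------
# Role assignment


def _heuristic_role(chain: Chain) -> ChainRole | None:
    n_std = chain.n_standard_residues
    if all(r.is_water for r in chain.residues):
        return ChainRole.WATER
    if n_std == 0:
        return ChainRole.HETERO
    if 8 <= n_std <= 11 and n_std == len(chain):
        return ChainRole.PEPTIDE
    if 95 <= n_std <= 105:
        return ChainRole.B2M
    if 270 <= n_std <= 285:
        return ChainRole.MHC_HEAVY
    return None


def assign_roles(
    model: StructureModel,
    overrides: Mapping[str, ChainRole | str] | None = None,
) -> ComplexDefinition:
    """Assign a biological role to every chain.

    Heuristics by chain length: 8-11 standard residues -> peptide,
    ~95-105 -> beta-2 microglobulin, ~270-285 -> MHC heavy chain, waters
    and pure-hetero chains by content. If exactly two protein chains
    remain they are taken as the TCR, the longer as ``tcr_beta`` (V+C
    beta constructs run longer than alpha). Equal-length leftovers
    without overrides raise :class:`RoleAssignmentError` — the package
    never silently guesses between TCR alpha and beta.

    ``overrides`` (chain_id -> role) win unconditionally.
    """
    overrides = {k: ChainRole(v) for k, v in (overrides or {}).items()}
    unknown = set(overrides) - set(model.chain_ids)
    if unknown:
        raise RoleAssignmentError(f"override for unknown chains: {sorted(unknown)}")

    roles: dict[str, ChainRole] = {}
    leftovers: list[Chain] = []
    for chain in model.chains:
        if chain.chain_id in overrides:
            roles[chain.chain_id] = overrides[chain.chain_id]
            continue
        role = _heuristic_role(chain)
        if role is None:
            leftovers.append(chain)
        else:
            roles[chain.chain_id] = role

    if leftovers:
        if len(leftovers) == 2:
            a, b = leftovers
            if len(a) == len(b):
                raise RoleAssignmentError(
                    "roles ambiguous: two equal-length candidate TCR chains "
                    f"{a.chain_id!r} and {b.chain_id!r}; supply overrides"
                )
            shorter, longer = sorted(leftovers, key=len)
            roles[shorter.chain_id] = ChainRole.TCR_ALPHA
            roles[longer.chain_id] = ChainRole.TCR_BETA
        elif len(leftovers) == 1:
            raise RoleAssignmentError(
                f"roles ambiguous: cannot classify chain {leftovers[0].chain_id!r} "
                f"({len(leftovers[0])} residues); supply overrides"
            )
        else:
            raise RoleAssignmentError(
                "roles ambiguous: cannot classify chains "
                f"{[c.chain_id for c in leftovers]}; supply overrides"
            )
    return ComplexDefinition(model=model, roles=roles)


# ---------------------------------------------------------------------------
# Selection

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_selector(selector: str | Mapping[str, object]) -> dict:
    """Selectors: ``"chain=A; resi=1-9; name=CA; role=peptide"`` (fields
    optional, ``;`` or whitespace separated, values comma-separated)."""
    if isinstance(selector, Mapping):
        sel = dict(selector)
    else:
        sel = {}
        if selector.strip() in ("", "all", "*"):
            return sel
        for tok in re.split(r"[;\s]+", selector.strip()):
            if not tok:
                continue
            if "=" not in tok:
                raise SelectionError(f"malformed selector token {tok!r}")
            key, value = tok.split("=", 1)
            key = key.strip().lower()
            if key not in ("chain", "resi", "name", "role"):
                raise SelectionError(f"unknown selector field {key!r}")
            sel.setdefault(key, []).extend(v.strip() for v in value.split(","))
    return sel


def _resi_match(seq_id: int, specs: list[str]) -> bool:
    for spec in specs:
        m = _RANGE_RE.match(str(spec))
        if not m:
            raise SelectionError(f"bad residue range {spec!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if lo <= seq_id <= hi:
            return True
    return False


def select(
    model: StructureModel | ComplexDefinition,
    selector: str | Mapping[str, object],
) -> StructureModel:
    """Subset a model by chain / residue range / atom name / role.

    Accepts a :class:`ComplexDefinition` when the selector uses ``role=``.
    The result preserves coordinates, B-factors and ordering; selecting
    everything returns an identical model. An empty match raises
    :class:`SelectionError`.
    """
    sel = _parse_selector(selector)
    if isinstance(model, ComplexDefinition):
        cx, model_ = model, model.model
    else:
        cx, model_ = None, model
    if "role" in sel and cx is None:
        raise SelectionError("role= selector requires a ComplexDefinition")

    wanted_roles = {ChainRole(r) for r in sel.get("role", [])} if "role" in sel else None
    chains_out: list[Chain] = []
    for chain in model_.chains:
        if "chain" in sel and chain.chain_id not in sel["chain"]:
            continue
        if wanted_roles is not None and cx.roles[chain.chain_id] not in wanted_roles:
            continue
        residues_out: list[Residue] = []
        for res in chain.residues:
            if "resi" in sel and not _resi_match(res.seq_id, sel["resi"]):
                continue
            atoms = res.atoms
            if "name" in sel:
                atoms = [a for a in atoms if a.name in sel["name"]]
            if atoms:
                residues_out.append(Residue(res.seq_id, res.name, list(atoms), res.icode))
        if residues_out:
            chains_out.append(Chain(chain.chain_id, residues_out))
    if not chains_out:
        raise SelectionError(f"selector {selector!r} matched nothing")
    return StructureModel(model_.identifier, chains_out, model_.resolution)


# ---------------------------------------------------------------------------
# Flat key-value complex config

def read_complex_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` config file.

    Recognised keys: ``role.<chain_id> = <role>``, and
    ``cdr.<alpha|beta>.<loop> = <lo>-<hi>`` residue ranges. Lines starting
    with ``#`` are comments. Returns ``{"roles": {...}, "cdr_ranges": {...}}``.
    """
    roles: dict[str, str] = {}
    cdr: dict[str, dict[str, tuple[int, int]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SelectionError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        parts = key.split(".")
        if parts[0] == "role" and len(parts) == 2:
            roles[parts[1]] = value
        elif parts[0] == "cdr" and len(parts) == 3:
            m = _RANGE_RE.match(value)
            if not m or m.group(2) is None:
                raise SelectionError(f"{path}:{lineno}: bad range {value!r}")
            cdr.setdefault(parts[1], {})[parts[2]] = (int(m.group(1)), int(m.group(2)))
        else:
            raise SelectionError(f"{path}:{lineno}: unknown key {key!r}")
    return {"roles": roles, "cdr_ranges": cdr}
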