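"""Structural model: atoms, chains, radii, selections and coordinate I/O.

Coordinates are read and written through gemmi, so standard PDB and mmCIF
conventions (author chain ids, author residue numbering, altlocs, insertion
codes) are honoured.  The in-memory model is deliberately small: an ordered
list of chains, each an ordered list of residues, each a list of
:class:`AtomRecord`.  All downstream measurements (superposition, pore
profiling, ring statistics) operate on :class:`AtomSet` views produced by
:func:`select`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

log = logging.getLogger("oligosym")

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "AtomSet",
    "StructureError",
    "SelectionError",
    "DEFAULT_RADII",
    "FALLBACK_RADIUS",
    "read_structure",
    "write_pdb",
    "assign_radii",
    "select",
]


class StructureError(ValueError):
    """Malformed or empty coordinate input."""


class SelectionError(KeyError):
    """A selection matched no atoms, or a probe atom is missing."""


#: HOLE-like "simple" van der Waals set (Å).  The study's pore profiles were
#: produced with HOLE defaults; this set is configurable per call.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.85,
    "N": 1.75,
    "O": 1.65,
    "S": 2.00,
    "P": 2.10,
    "H": 1.00,
}

FALLBACK_RADIUS: float = 2.00

#: Residue names treated as water when filtering hetero atoms.
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: np.ndarray  # shape (3,), Å
    vdw: float | None = None
    icode: str = ""
    occupancy: float = 1.0
    het: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")
        if self.vdw is not None and self.vdw <= 0:
            raise StructureError(f"non-positive vdw radius for atom {self.serial}")


@dataclass
class Residue:
    name: str
    seq: int
    icode: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq == seq and r.icode == icode:
                return r
        return None


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    axis_hint: tuple[np.ndarray, np.ndarray] | None = None  # (point, unit dir)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def atoms(self) -> Iterable[AtomRecord]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        st = Structure(self.id, axis_hint=self.axis_hint)
        for c in self.chains:
            cc = Chain(c.id)
            for r in c.residues:
                rr = Residue(r.name, r.seq, r.icode)
                rr.atoms = [replace(a, xyz=a.xyz.copy()) for a in r.atoms]
                cc.residues.append(rr)
            st.chains.append(cc)
        return st


@dataclass
class AtomSet:
    """Ordered view over atoms, with the selection expression as provenance."""

    atoms: list[AtomRecord]
    expression: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        rs = []
        for a in self.atoms:
            if a.vdw is None:
                raise StructureError(
                    f"atom {a.chain_id}/{a.res_seq}/{a.name} has no vdw radius; "
                    "call assign_radii first"
                )
            rs.append(a.vdw)
        return np.asarray(rs, dtype=float)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [(a.chain_id, a.res_seq, a.icode, a.name) for a in self.atoms]


# ---------------------------------------------------------------------------
# Parsing


def _from_gemmi(st: gemmi.Structure, sid: str) -> Structure:
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{sid}: no models")
    model = st[0]
    out = Structure(sid or st.name or "structure")
    serial = 0
    by_id: dict[str, Chain] = {}
    for ch in model:
        # gemmi may split one author chain into polymer/water subchains
        chain = by_id.get(ch.name)
        new_chain = chain is None
        if new_chain:
            chain = Chain(ch.name)
        for res in ch:
            seq = res.seqid.num
            icode = (res.seqid.icode or " ").strip()
            rr = Residue(res.name, seq, icode)
            # altloc rule: one atom per name, highest occupancy, ties -> 'A'
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                else:
                    key_new = (at.occ, -ord(at.altloc or "A"))
                    key_old = (prev.occ, -ord(prev.altloc or "A"))
                    if key_new > key_old:
                        by_name[at.name] = at
            for at in by_name.values():
                serial += 1
                rr.atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        res_name=res.name,
                        res_seq=seq,
                        chain_id=ch.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        icode=icode,
                        occupancy=at.occ,
                        het=res.het_flag == "H",
                    )
                )
            if rr.atoms:
                chain.residues.append(rr)
        if chain.residues and new_chain:
            by_id[ch.name] = chain
            out.chains.append(chain)
    if out.n_atoms() == 0:
        raise StructureError(f"{sid}: structure contains zero atoms")
    return out


def read_structure(source: str | Path, format: str | None = None, id: str | None = None) -> Structure:
    """Read a PDB or mmCIF file (or literal text) into a :class:`Structure`.

    ``format`` is ``"pdb"`` or ``"mmcif"``; when omitted it is inferred from
    the file suffix.  Alternate locations are resolved to a single conformer
    (highest occupancy, ties broken toward altloc ``A``).
    """
    text: str | None = None
    path = Path(source) if not ("\n" in str(source)) else None
    if path is not None and path.exists():
        sid = id or path.stem
        if format is None:
            format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
        text = path.read_text()
    else:
        text = str(source)
        sid = id or "structure"
        if format is None:
            format = "mmcif" if text.lstrip().startswith(("data_", "#")) else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as e:  # gemmi raises RuntimeError on bad records
        raise StructureError(f"failed to parse {sid} as {format}: {e}") from e
    return _from_gemmi(st, sid)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for c in s.chains:
        ch = gemmi.Chain(c.id)
        for r in c.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seq, r.icode or " ")
            res.het_flag = "H" if (r.atoms and r.atoms[0].het) else "A"
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = a.occupancy
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as a standard single-model PDB file."""
    _to_gemmi(s).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Radii


def assign_radii(
    s: Structure,
    table: Mapping[str, float] | None = None,
    fallback: float = FALLBACK_RADIUS,
    include_hydrogens: bool = False,
) -> Structure:
    """Return a copy of ``s`` with every atom's vdw radius set from ``table``.

    Unknown elements receive ``fallback`` and a warning is emitted once per
    element.  Hydrogens keep their radius but are excluded from pore
    calculations by default (see :mod:`oligosym.pore`).
    """
    tab = dict(DEFAULT_RADII if table is None else table)
    for el, r in tab.items():
        if r <= 0:
            raise StructureError(f"non-positive radius {r} for element {el!r}")
    if fallback <= 0:
        raise StructureError("non-positive fallback radius")
    out = s.copy()
    warned: set[str] = set()
    for a in out.atoms():
        el = a.element.upper() if a.element else a.name[:1].upper()
        if el in tab:
            a.vdw = tab[el]
        else:
            a.vdw = fallback
            if el not in warned:
                warned.add(el)
                msg = f"element {el!r} not in radius table; using fallback {fallback} Å"
                log.warning(msg)
                warnings.warn(msg, stacklevel=2)
    _ = include_hydrogens  # recorded for symmetry with pore options
    return out


# ---------------------------------------------------------------------------
# Selection


def select(
    s: Structure,
    chains: Sequence[str] | None = None,
    res_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] | None = None,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> AtomSet:
    """Select atoms matching the conjunction of the provided filters.

    Residue ranges are inclusive and use author numbering.  Waters and hetero
    residues are excluded unless explicitly requested.  Order is deterministic:
    chain order, then residue order, then atom-name order within a residue.
    """
    parts = []
    if chains is not None:
        parts.append(f"chains={list(chains)}")
    if res_range is not None:
        parts.append(f"res_range={list(res_range)}")
    if atom_names is not None:
        parts.append(f"atom_names={list(atom_names)}")
    expr = " and ".join(parts) or "all"

    chain_set = set(chains) if chains is not None else None
    name_set = set(atom_names) if atom_names is not None else None
    picked: list[AtomRecord] = []
    for c in s.chains:
        if chain_set is not None and c.id not in chain_set:
            continue
        for r in c.residues:
            if r.name in WATER_NAMES and not include_waters:
                continue
            if res_range is not None and not (res_range[0] <= r.seq <= res_range[1]):
                continue
            for a in sorted(r.atoms, key=lambda a: a.name):
                if a.het and not include_hetero and a.res_name not in WATER_NAMES:
                    continue
                if a.res_name in WATER_NAMES and not include_waters:
                    continue
                if name_set is not None and a.name not in name_set:
                    continue
                picked.append(a)
    if not picked:
        raise SelectionError(f"selection matched no atoms: {expr}")
    return AtomSet(picked, expr)


def paired_sets(a: Structure, b: Structure, **kwargs) -> tuple[AtomSet, AtomSet]:
    """Select the same expression in two structures and pair atoms by
    (chain, res_seq, icode, atom name), keeping only keys present in both."""
    sa = select(a, **kwargs)
    sb = select(b, **kwargs)
    keys_a = {k: at for k, at in zip(sa.keys(), sa.atoms)}
    keys_b = {k: at for k, at in zip(sb.keys(), sb.atoms)}
    shared = [k for k in sa.keys() if k in keys_b]
    if not shared:
        raise SelectionError("no shared atoms between structures for pairing")
    return (
        AtomSet([keys_a[k] for k in shared], sa.expression),
        AtomSet([keys_b[k] for k in shared], sb.expression),
    )
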