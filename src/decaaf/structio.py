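"""Protein structure I/O and residue/atom addressing.

Structures are held in lightweight containers (:class:`Atom`,
:class:`Residue`, :class:`Structure`) that keep exactly what active-site
motif matching needs: author residue numbering with insertion codes,
atom names, coordinates, and optional per-atom charges (from PQR) and
electrostatic potentials (assigned later, in kT/e).

PDB files are parsed and written through :mod:`gemmi`; the whitespace
PQR dialect (PDB-like records with charge and radius columns) has its
own small reader since gemmi does not handle it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ReactiveAtomMap",
    "DEFAULT_REACTIVE_ATOMS",
    "WATER_NAMES",
    "load_structure",
    "write_structure",
    "get_reactive_atom",
    "is_water",
    "parse_residue_label",
]

#: Residue names treated as water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_AA3 = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}


class StructureError(ValueError):
    """Raised for unreadable files, missing atoms/residues, bad addresses."""


@dataclass
class Atom:
    """A single atom: name, element, coordinates (Å), optional charge (e)
    and electrostatic potential (kT/e, unset until assigned)."""

    serial: int
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    charge: float | None = None
    radius: float | None = None
    potential: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coord must be 3 finite components")
        if not self.name:
            raise StructureError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue addressed by (chain, author number, insertion code)."""

    chain_id: str
    number: int
    name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def address(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        """Human label as used in the literature, e.g. ``Ser195``."""
        pretty = _AA3.get(self.name.upper(), self.name.upper())
        return f"{pretty}{self.number}{self.insertion_code}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(
            f"residue {self.label} has no atom {name!r} (incomplete side chain?)"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """An ordered collection of residues from one model of one file."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.address in seen:
                raise StructureError(f"duplicate residue address {r.address}")
            seen.add(r.address)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def residue(self, chain: str | None, number: int, icode: str = "") -> Residue:
        """Look up a residue; ``chain=None`` searches all chains (first hit)."""
        for r in self.residues:
            if r.number == number and r.insertion_code == icode:
                if chain is None or r.chain_id == chain:
                    return r
        where = f"chain {chain}" if chain is not None else "any chain"
        raise StructureError(f"no residue {number}{icode} in {where} of {self.id}")

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[
                replace(r, atoms=[replace(a, coord=a.coord.copy()) for a in r.atoms])
                for r in self.residues
            ],
            source_path=self.source_path,
        )


@dataclass(frozen=True)
class ReactiveAtomMap:
    """Residue name → reactive-atom name.

    The reactive atom is the single functionally relevant atom that
    represents a residue in motif matching (Ser/OG, His/ND1, Gly/N, ...).
    Unmapped residue names fall back to CA so every residue stays
    addressable.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    fallback: str = "CA"

    def atom_name(self, residue_name: str, override: str | None = None) -> str:
        if override:
            return override
        return self.mapping.get(residue_name.upper(), self.fallback)


#: Default reactive atoms; His uses the ND1 tautomer nitrogen.
DEFAULT_REACTIVE_ATOMS = ReactiveAtomMap(
    mapping={
        "SER": "OG", "THR": "OG1", "TYR": "OH", "CYS": "SG",
        "HIS": "ND1", "LYS": "NZ", "ARG": "NH1",
        "ASP": "OD1", "GLU": "OE1", "ASN": "OD1", "GLN": "OE1",
        "GLY": "N", "ALA": "N",
    }
)


def is_water(r: Residue, names: frozenset[str] = WATER_NAMES) -> bool:
    """True iff the residue is a water molecule (HOH/WAT/DOD by default)."""
    return r.name.upper() in names


def parse_residue_label(label: str) -> tuple[str, int]:
    """Parse ``'Ser195'`` → ``('SER', 195)``."""
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    name, num = label[:i], label[i:]
    if not name or not num:
        raise ValueError(f"cannot parse residue label {label!r}")
    return name.upper(), int(num)


def _resolve_altlocs(atoms: list[Atom], altlocs: list[str], policy: str) -> list[Atom]:
    # Group by atom name; keep one conformer per name.
    if policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    chosen: dict[str, Atom] = {}
    order: list[str] = []
    for atom, alt in zip(atoms, altlocs):
        if atom.name not in chosen:
            chosen[atom.name] = atom
            order.append(atom.name)
        elif policy == "occupancy" and atom.occupancy > chosen[atom.name].occupancy:
            chosen[atom.name] = atom
    return [chosen[n] for n in order]


def _from_gemmi(st: gemmi.Structure, model_index: int, altloc_policy: str,
                source: str) -> Structure:
    if len(st) == 0:
        raise StructureError(f"no atoms in {source}")
    if not 0 <= model_index < len(st):
        raise StructureError(
            f"model index {model_index} out of range ({len(st)} models in {source})"
        )
    model = st[model_index]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            raw, alts = [], []
            for at in res:
                raw.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                    )
                )
                alts.append(at.altloc)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    name=res.name,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atoms=_resolve_altlocs(raw, alts, altloc_policy),
                )
            )
    if not any(r.atoms for r in residues):
        raise StructureError(f"no atoms in {source}")
    sid = st.name or os.path.splitext(os.path.basename(source))[0]
    return Structure(id=sid, residues=residues, source_path=source)


def _load_pqr(path: str) -> Structure:
    """Whitespace-dialect PQR: ATOM/HETATM serial name resname [chain]
    resnum x y z charge radius."""
    residues: dict[tuple[str, int, str], Residue] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            # Chain id is optional in PQR output; detect by field count.
            if len(parts) == 11:
                _, serial, name, resname, chain, resnum, x, y, z, q, r = parts
            elif len(parts) == 10:
                _, serial, name, resname, resnum, x, y, z, q, r = parts
                chain = ""
            else:
                raise StructureError(f"unparseable PQR line: {line.rstrip()!r}")
            addr = (chain, int(resnum), "")
            res = residues.get(addr)
            if res is None:
                res = residues[addr] = Residue(
                    chain_id=chain, number=int(resnum), name=resname
                )
            res.atoms.append(
                Atom(
                    serial=int(serial),
                    name=name,
                    element=name[0],
                    coord=np.array([float(x), float(y), float(z)]),
                    charge=float(q),
                    radius=float(r),
                )
            )
    if not residues:
        raise StructureError(f"no atoms in {path}")
    sid = os.path.splitext(os.path.basename(path))[0]
    return Structure(id=sid, residues=list(residues.values()), source_path=path)


def load_structure(path: str, model_index: int = 0,
                   altloc_policy: str = "occupancy") -> Structure:
    """Read a PDB or PQR file into a :class:`Structure`.

    Parameters
    ----------
    path
        PDB (``.pdb``/``.ent``) or PQR (``.pqr``) file.
    model_index
        Which MODEL of a multi-model (e.g. NMR) file to keep; default the
        first.
    altloc_policy
        ``"occupancy"`` keeps the highest-occupancy alternate location
        (ties → first in file); ``"first"`` always keeps the first.
    """
    if not os.path.exists(path):
        raise StructureError(f"file not found: {path}")
    if path.lower().endswith(".pqr"):
        return _load_pqr(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st, model_index, altloc_policy, path)


def write_structure(s: Structure, path: str) -> None:
    """Write a Structure as PDB (coordinates at the format's 3-decimal
    precision); waters and HETATMs are emitted as gemmi classifies them."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in s.residues:
        cid = r.chain_id or "A"
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
        if is_water(r):
            res.het_flag = "H"
        for a in r.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element or a.name[0])
            at.pos = gemmi.Position(*a.coord)
            at.occ = a.occupancy
            at.serial = a.serial
            res.add_atom(at)
        chains[cid].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(path)


def get_reactive_atom(
    s: Structure,
    residue_spec: tuple[str | None, int, str],
    amap: ReactiveAtomMap = DEFAULT_REACTIVE_ATOMS,
    override: str | None = None,
) -> Atom:
    """Return the reactive atom of the residue addressed by
    ``(chain, number, residue name)``; an explicit ``override`` atom name
    wins over the map."""
    chain, number, resname = residue_spec
    res = s.residue(chain, number)
    if resname and res.name.upper() != resname.upper():
        raise StructureError(
            f"residue {number} in {s.id} is {res.name}, expected {resname}"
        )
    return res.atom(amap.atom_name(res.name, override))
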