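"""Template motifs, partial-motif libraries, stereochemical equivalence.

A template motif is an ordered set of N ≥ 3 active-site residues of the
template enzyme, each represented by one reactive atom, together with all
pairwise reference distances (Å) and, when a potential source is given,
pairwise reference potential differences (kT/e, earlier position minus
later).  Partial motifs are the order-preserved k-subsets (3 ≤ k ≤ N);
the size-k library has C(N, k) members.

A motif position may be widened to accept stereochemically equivalent
residue types (e.g. the hydroxyl nucleophiles Ser and Tyr, or Gly↔Ala
matched through the backbone nitrogen); the reactive atom of each allowed
type comes from the reactive-atom map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import yaml

from .potentials import PotentialSource, assign_potentials
from .structio import (
    DEFAULT_REACTIVE_ATOMS,
    ReactiveAtomMap,
    Structure,
    parse_residue_label,
)

__all__ = [
    "MotifPosition",
    "TemplateMotif",
    "PartialMotif",
    "EQUIVALENCE_PRESETS",
    "build_template",
    "enumerate_partial_motifs",
    "expand_equivalence",
    "load_motif_file",
]

#: Stereochemical equivalence classes (opt-in, per position).
EQUIVALENCE_PRESETS: dict[str, frozenset[str]] = {
    "nucleophile": frozenset({"SER", "THR", "TYR", "CYS"}),
    "carboxylate": frozenset({"ASP", "GLU"}),
    "amide": frozenset({"ASN", "GLN"}),
    "small": frozenset({"GLY", "ALA"}),
    "cation": frozenset({"LYS", "ARG"}),
}


@dataclass(frozen=True)
class MotifPosition:
    """One motif position: a template residue, its reactive atom, and the
    residue types allowed to occupy the position in a target."""

    label: str                              # e.g. "Ser195"
    residue_spec: tuple[str | None, int, str]
    atom_name: str
    allowed_atoms: dict[str, str] = field(default_factory=dict)  # resname → atom

    def __post_init__(self) -> None:
        if not self.allowed_atoms:
            object.__setattr__(
                self, "allowed_atoms", {self.residue_spec[2].upper(): self.atom_name}
            )

    @property
    def allowed_residues(self) -> frozenset[str]:
        return frozenset(self.allowed_atoms)


@dataclass(frozen=True)
class TemplateMotif:
    """Ordered motif positions with reference pairwise distances (Å) and
    optional reference potential differences (kT/e, position order)."""

    positions: tuple[MotifPosition, ...]
    ref_distances: dict[tuple[int, int], float]     # i < j, Å
    ref_pds: dict[tuple[int, int], float] | None = None
    structure_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n < 3:
            raise ValueError(f"a motif needs at least 3 positions, got {n}")
        expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
        if set(self.ref_distances) != expected:
            raise ValueError("ref_distances must cover all ordered pairs")
        if any(d <= 0 for d in self.ref_distances.values()):
            raise ValueError("reference distances must be positive")

    @property
    def size(self) -> int:
        return len(self.positions)

    def distance(self, i: int, j: int) -> float:
        return self.ref_distances[(i, j) if i < j else (j, i)]

    def pd(self, i: int, j: int) -> float:
        if self.ref_pds is None:
            raise ValueError("motif has no reference potential differences")
        return self.ref_pds[(i, j)] if i < j else -self.ref_pds[(j, i)]


@dataclass(frozen=True)
class PartialMotif:
    """An order-preserved k-subset of a parent motif; reference values are
    the parent's, restricted to the subset (never recomputed)."""

    parent: TemplateMotif
    index_subset: tuple[int, ...]

    def __post_init__(self) -> None:
        k, n = len(self.index_subset), self.parent.size
        if not 3 <= k <= n:
            raise ValueError(f"partial motif size {k} outside [3, {n}]")
        if list(self.index_subset) != sorted(set(self.index_subset)):
            raise ValueError("index subset must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.index_subset)

    @property
    def positions(self) -> tuple[MotifPosition, ...]:
        return tuple(self.parent.positions[i] for i in self.index_subset)

    @property
    def label(self) -> str:
        return "-".join(p.label for p in self.positions)

    def distance(self, i: int, j: int) -> float:
        """Reference distance between local positions i < j."""
        return self.parent.distance(self.index_subset[i], self.index_subset[j])

    def pd(self, i: int, j: int) -> float:
        return self.parent.pd(self.index_subset[i], self.index_subset[j])

    @property
    def has_pds(self) -> bool:
        return self.parent.ref_pds is not None


def build_template(
    s: Structure,
    residue_specs: list,
    amap: ReactiveAtomMap = DEFAULT_REACTIVE_ATOMS,
    src: PotentialSource | None = None,
    atom_overrides: dict[str, str] | None = None,
) -> TemplateMotif:
    """Build a template motif from active-site residues of a structure.

    ``residue_specs`` entries are either labels like ``"Ser195"`` (any
    chain) or tuples ``(chain, number, resname)``.  ``atom_overrides``
    maps a label to an explicit reactive-atom name (e.g. backbone ``"N"``).
    Potential differences are computed iff a potential source is given.
    """
    atom_overrides = atom_overrides or {}
    if src is not None:
        assign_potentials(s, src)
    positions, atoms = [], []
    for spec in residue_specs:
        if isinstance(spec, str):
            resname, number = parse_residue_label(spec)
            chain = None
        else:
            chain, number, resname = spec
        res = s.residue(chain, number)
        if res.name.upper() != resname.upper():
            raise ValueError(
                f"residue {number} in {s.id} is {res.name}, expected {resname}"
            )
        label = res.label
        atom_name = amap.atom_name(res.name, atom_overrides.get(label))
        atom = res.atom(atom_name)
        positions.append(
            MotifPosition(
                label=label,
                residue_spec=(res.chain_id, res.number, res.name.upper()),
                atom_name=atom_name,
            )
        )
        atoms.append(atom)

    n = len(positions)
    if n < 3:
        raise ValueError(f"a motif needs at least 3 positions, got {n}")
    ref_distances = {
        (i, j): float(np.linalg.norm(atoms[i].coord - atoms[j].coord))
        for i in range(n) for j in range(i + 1, n)
    }
    ref_pds = None
    if src is not None:
        ref_pds = {
            (i, j): atoms[i].potential - atoms[j].potential
            for i in range(n) for j in range(i + 1, n)
        }
    return TemplateMotif(
        positions=tuple(positions),
        ref_distances=ref_distances,
        ref_pds=ref_pds,
        structure_id=s.id,
    )


def enumerate_partial_motifs(m: TemplateMotif, k: int) -> list[PartialMotif]:
    """All C(N, k) order-preserved k-subsets, in lexicographic order."""
    if not 3 <= k <= m.size:
        raise ValueError(f"k={k} outside [3, {m.size}]")
    return [PartialMotif(m, subset) for subset in combinations(range(m.size), k)]


def expand_equivalence(
    m: TemplateMotif,
    position_label: str,
    extra_residues: set[str] | frozenset[str],
    amap: ReactiveAtomMap = DEFAULT_REACTIVE_ATOMS,
) -> TemplateMotif:
    """Allow additional residue types at the named position.

    Each added type matches through its own mapped reactive atom
    (Ser→OG but Tyr→OH); the template's reference geometry is unchanged.
    """
    labels = [p.label for p in m.positions]
    if position_label not in labels:
        raise ValueError(f"no position {position_label!r} in motif {labels}")
    idx = labels.index(position_label)
    pos = m.positions[idx]
    allowed = dict(pos.allowed_atoms)
    for resname in extra_residues:
        allowed[resname.upper()] = amap.atom_name(resname)
    new_pos = replace(pos, allowed_atoms=allowed)
    return replace(
        m, positions=m.positions[:idx] + (new_pos,) + m.positions[idx + 1:]
    )


def load_motif_file(path: str, amap: ReactiveAtomMap = DEFAULT_REACTIVE_ATOMS):
    """Read a motif definition (YAML list of positions).

    Each entry: ``residue`` (label like Ser195) or ``chain``/``number``/
    ``name``; optional ``atom`` override and ``allowed`` extra residue
    types.  Returns (residue_specs, atom_overrides, expansions) ready for
    :func:`build_template` / :func:`expand_equivalence`.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    specs, overrides, expansions = [], {}, {}
    for e in entries:
        if "residue" in e:
            resname, number = parse_residue_label(e["residue"])
            chain = e.get("chain")
        else:
            chain, number, resname = e.get("chain"), e["number"], e["name"].upper()
        specs.append((chain, number, resname))
        label = f"{resname.capitalize()}{number}"
        if "atom" in e:
            overrides[label] = e["atom"]
        if "allowed" in e:
            expansions[label] = {r.upper() for r in e["allowed"]} - {resname.upper()}
    return specs, overrides, expansions
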