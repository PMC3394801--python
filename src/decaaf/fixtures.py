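"""Synthetic structures for testing the whole pipeline without downloads.

Three generators:

* :func:`make_anchor_fixture` — minimal structures carrying the published
  active-site anchor atoms of human neutrophil elastase (PDB 1B0F:
  Ser195/OG, His57/ND1, Ser214/OG) and of the tomato PR-1 protein P14A
  (PDB 1CFE: Ser49/OG, His48/ND1, Tyr36/OH), with backbone stubs so the
  residues parse and write as normal PDB.
* :func:`plant_motif` — embeds a noisy copy of a template motif's
  reactive-atom geometry among random decoy residues under a random
  rigid motion, recording the ground-truth assignment.
* :func:`make_glu166_site_fixture` — a synthetic reconstruction of the
  Ω-loop neighborhood around Glu166/OE1 in a Class A β-lactamase
  (geometry mimicking PDB entry 1E25): atom distances to OE1 match the
  published neighbor distances, with the first water at 3.1 Å and the
  flanking residues Ala167/Gln168 beyond 3 Å.

None of these aim for physically realistic backbone geometry; they give
exact, reproducible reactive-atom configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .motifs import TemplateMotif
from .structio import Atom, Residue, Structure

__all__ = [
    "PlantSpec",
    "PlantedMotif",
    "make_anchor_fixture",
    "hne_extended_motif",
    "plant_motif",
    "make_glu166_site_fixture",
]

# Published anchor coordinates (Å) of the elastase/P14A partial match.
_ANCHORS = {
    "hne_1b0f": (
        "1B0F",
        [
            ("SER", 195, "OG", (64.4, 57.0, 53.8)),
            ("HIS", 57, "ND1", (63.3, 54.8, 58.2)),
            ("SER", 214, "OG", (63.6, 50.6, 56.1)),
        ],
    ),
    "p14a_1cfe": (
        "1CFE",
        [
            ("SER", 49, "OG", (8.8, -6.3, -4.8)),
            ("HIS", 48, "ND1", (9.2, -2.4, -1.8)),
            ("TYR", 36, "OH", (13.7, -1.6, -3.7)),
        ],
    ),
}

#: 20 standard residue names decoys are drawn from.
_STANDARD = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

_ELEMENT = {"O": "O", "N": "N", "S": "S", "C": "C"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


def _stub_residue(name: str, number: int, key_atom: str, coord,
                  serial_start: int, chain: str = "A") -> Residue:
    """A residue with the key atom at the exact coordinate plus N/CA/C
    backbone stubs offset by ~1.5 Å so the residue parses as a normal
    amino acid.  When the key atom is itself the backbone N, only CA/C
    stubs are added."""
    coord = np.asarray(coord, dtype=float)
    atoms = [
        Atom(serial=serial_start, name=key_atom, element=_element_of(key_atom),
             coord=coord)
    ]
    offsets = {"N": (1.5, 0.0, 0.0), "CA": (1.5, 1.5, 0.0), "C": (3.0, 1.5, 0.0)}
    nxt = serial_start + 1
    for bb, off in offsets.items():
        if bb == key_atom:
            continue
        atoms.append(
            Atom(serial=nxt, name=bb, element="N" if bb == "N" else "C",
                 coord=coord + np.array(off))
        )
        nxt += 1
    return Residue(chain_id=chain, number=number, name=name, atoms=atoms)


def make_anchor_fixture(which: str) -> Structure:
    """Structure holding exactly the three published anchor atoms of the
    chosen protein (``hne_1b0f`` or ``p14a_1cfe``), plus backbone stubs."""
    if which not in _ANCHORS:
        raise ValueError(f"unknown fixture {which!r}; choose from {sorted(_ANCHORS)}")
    sid, rows = _ANCHORS[which]
    residues = []
    serial = 1
    for name, number, atom_name, coord in rows:
        residues.append(_stub_residue(name, number, atom_name, coord, serial))
        serial += 4
    residues.sort(key=lambda r: r.number)
    return Structure(id=sid, residues=residues, source_path=f"fixture:{which}")


def hne_extended_motif() -> TemplateMotif:
    """The extended human-neutrophil-elastase scaffold
    (Ser195/OG, His57/ND1, Ser214/OG, Gly193/N) as a template motif built
    from its published pairwise reactive-atom distances (Å).

    Unlike the near-isoceles Ser-His-Ser triangle, the four-residue
    scaffold has well-separated pairwise distances, so a planted copy has
    a unique best assignment even under noise — the right template for
    recovery studies.
    """
    from .motifs import MotifPosition

    positions = (
        MotifPosition("Ser195", ("A", 195, "SER"), "OG"),
        MotifPosition("His57", ("A", 57, "HIS"), "ND1"),
        MotifPosition("Ser214", ("A", 214, "SER"), "OG"),
        MotifPosition("Gly193", ("A", 193, "GLY"), "N"),
    )
    ref = {(0, 1): 5.0, (0, 2): 6.8, (0, 3): 4.6,
           (1, 2): 4.7, (1, 3): 9.4, (2, 3): 11.0}
    return TemplateMotif(positions=positions, ref_distances=ref,
                         structure_id="1B0F")


@dataclass(frozen=True)
class PlantSpec:
    """Controls for planting a motif copy in a decoy structure.

    ``noise_sigma`` (Å) is the isotropic Gaussian noise added to each
    planted reactive atom; ``decoy_residue_count`` random residues are
    scattered at ~0.01 residues/Å³ (dense enough to produce near-miss
    candidates); a random proper rigid motion is applied unless
    ``rigid_motion`` is False.
    """

    noise_sigma: float = 0.0
    decoy_residue_count: int = 30
    seed: int = 0
    rigid_motion: bool = True

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.decoy_residue_count < 0:
            raise ValueError("decoy_residue_count must be >= 0")


@dataclass
class PlantedMotif:
    """A decoy structure with the planted copy's ground truth."""

    structure: Structure
    assignment: list[tuple[str, int]]           # (chain, resnum) per position
    perturbations: np.ndarray                   # (k, 3) noise actually applied, Å


def _template_geometry(template: TemplateMotif) -> np.ndarray:
    """Reconstruct reactive-atom coordinates realizing the motif's
    reference distances (the template's own geometry up to rigid motion),
    via classical multidimensional scaling of the distance matrix."""
    n = template.size
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = template.distance(i, j) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(gram)
    w = np.clip(w[::-1][:3], 0, None)
    v = v[:, ::-1][:, :3]
    return v * np.sqrt(w)


def plant_motif(template: TemplateMotif, spec: PlantSpec) -> PlantedMotif:
    """Embed a (noisy) copy of the template's reactive-atom geometry in a
    random decoy structure; deterministic under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    k = template.size
    coords = _template_geometry(template)

    perturbations = rng.normal(0.0, spec.noise_sigma, size=(k, 3)) \
        if spec.noise_sigma > 0 else np.zeros((k, 3))
    planted = coords + perturbations

    n_decoys = spec.decoy_residue_count
    box = (max(n_decoys, 1) / 0.01) ** (1 / 3)
    decoy_names = rng.choice(_STANDARD, size=n_decoys)
    decoy_pos = rng.uniform(-box / 2, box / 2, size=(n_decoys, 3))

    if spec.rigid_motion:
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-50, 50, size=3)
        planted = planted @ rot.T + trans
        decoy_pos = decoy_pos @ rot.T + trans

    residues: list[Residue] = []
    assignment: list[tuple[str, int]] = []
    serial = 1
    number = 1
    for pos, xyz in zip(template.positions, planted):
        resname = pos.residue_spec[2]
        residues.append(_stub_residue(resname, number, pos.atom_name, xyz, serial))
        assignment.append(("A", number))
        serial += 4
        number += 1
    from .structio import DEFAULT_REACTIVE_ATOMS
    for name, xyz in zip(decoy_names, decoy_pos):
        atom_name = DEFAULT_REACTIVE_ATOMS.atom_name(name)
        residues.append(_stub_residue(str(name), number, atom_name, xyz, serial))
        serial += 4
        number += 1

    s = Structure(
        id=f"planted-seed{spec.seed}",
        residues=residues,
        source_path="fixture:planted",
    )
    return PlantedMotif(structure=s, assignment=assignment,
                        perturbations=perturbations)


def make_glu166_site_fixture() -> Structure:
    """Synthetic reconstruction of the deacylation-base neighborhood in a
    Class A β-lactamase (PDB 1E25-like), centered on Glu166/OE1.

    The Glu166 side-chain/backbone atoms and the first water are placed
    at the published distances from OE1 (CD 1.3, OE2 2.2, CG 2.4, CB 2.7,
    CA 3.0, HOH2076 O 3.1 Å), in chemically sensible directions; the
    flanking Ala167 and Gln168 sit beyond 3 Å, so the catalytic atom is
    sterically unobstructed.  Synthetic stand-in: distances, not the
    deposited coordinates, are authoritative here.
    """
    o = np.zeros(3)

    def at(d: float, direction) -> np.ndarray:
        u = np.asarray(direction, dtype=float)
        return o + d * u / np.linalg.norm(u)

    glu = Residue(
        chain_id="A", number=166, name="GLU",
        atoms=[
            Atom(serial=1, name="OE1", element="O", coord=o),
            Atom(serial=2, name="CD", element="C", coord=at(1.3, (1, 0, 0))),
            Atom(serial=3, name="OE2", element="O", coord=at(2.2, (1, 0.9, 0))),
            Atom(serial=4, name="CG", element="C", coord=at(2.4, (1, -0.8, 0.2))),
            Atom(serial=5, name="CB", element="C", coord=at(2.7, (1, -1.2, 1.0))),
            Atom(serial=6, name="CA", element="C", coord=at(3.0, (1, -1.5, 1.8))),
            Atom(serial=7, name="C", element="C", coord=at(3.9, (1, -1.6, 2.4))),
            Atom(serial=8, name="N", element="N", coord=at(3.6, (0.6, -1.8, 1.6))),
        ],
    )
    ala = _stub_residue("ALA", 167, "CB", at(6.5, (0.8, -1.0, 2.8)), 9)
    gln = _stub_residue("GLN", 168, "OE1", at(7.5, (-0.5, -1.4, 2.2)), 13)
    wat = Residue(
        chain_id="A", number=2076, name="HOH",
        atoms=[Atom(serial=17, name="O", element="O", coord=at(3.1, (0.2, 1.4, 1.0)))],
    )
    far_wat = Residue(
        chain_id="A", number=2200, name="HOH",
        atoms=[Atom(serial=18, name="O", element="O", coord=at(4.4, (-1.0, 0.8, 0.4)))],
    )
    return Structure(
        id="1E25-site-synthetic",
        residues=[glu, ala, gln, wat, far_wat],
        source_path="fixture:glu166_site",
    )
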