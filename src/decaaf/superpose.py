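"""Canonical-frame superposition, steric neighborhoods, mutation proposals.

The superposition is the exact 3-anchor frame construction, not a
least-squares fit: each structure is rigidly moved so that its first
anchor atom sits at the origin, its second on the +X axis, and its third
in the Z = 0 plane with positive Y.  Two structures whose anchor triples
have congruent geometry then overlap near the anchors; matched pairs not
used as anchors, and any systematic strain, show up as residual
distances in the summary.

Matching by pairwise distances alone cannot distinguish enantiomeric
sites; since the frame construction never reflects, a mirror-image site
will superpose its anchors exactly but place the remaining atoms on the
wrong side — visible as large residuals on extra matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, Residue, Structure, is_water

__all__ = [
    "RigidTransform",
    "canonical_frame",
    "superpose_pair",
    "NeighborReport",
    "neighbor_report",
    "MutationSuggestion",
    "suggest_mutations",
    "steric_obstruction_compare",
]

#: Anchors closer to collinear than this triangle height (Å) are rejected.
COLLINEARITY_TOL = 1e-6


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R (x − shift); det(R) = +1."""

    rotation: np.ndarray    # (3, 3) proper orthogonal
    shift: np.ndarray       # (3,) point mapped to the origin

    def apply(self, coords: np.ndarray) -> np.ndarray:
        pts = np.asarray(coords, dtype=float)
        return (pts - self.shift) @ self.rotation.T

    def transform_structure(self, s: Structure) -> Structure:
        out = s.copy()
        for a in out.atoms:
            a.coord = self.apply(a.coord)
        return out


def canonical_frame(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> RigidTransform:
    """Rigid motion taking anchor a → origin, b → +X axis, c → Z = 0
    plane with Y > 0.

    The rotation rows are the orthonormal frame (e1 along b−a, e2 the
    in-plane component of c−a, e3 = e1 × e2), so the transform is always
    a proper rotation — chirality is preserved.  Raises
    :class:`GeometryError` for coincident or collinear anchors.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    e1 = b - a
    n1 = np.linalg.norm(e1)
    if n1 < COLLINEARITY_TOL:
        raise GeometryError("anchors a and b coincide")
    e1 = e1 / n1
    v = c - a
    rej = v - (v @ e1) * e1
    height = np.linalg.norm(rej)
    if height < COLLINEARITY_TOL:
        raise GeometryError("anchors are collinear (or c coincides with a)")
    e2 = rej / height
    e3 = np.cross(e1, e2)
    return RigidTransform(rotation=np.vstack([e1, e2, e3]), shift=a)


def superpose_pair(
    template: Structure,
    t_anchors: tuple[Atom, Atom, Atom],
    target: Structure,
    g_anchors: tuple[Atom, Atom, Atom],
    extra_pairs: list[tuple[Atom, Atom]] | None = None,
) -> tuple[Structure, Structure, dict]:
    """Superpose two structures on a 3-atom partial match.

    Both whole structures are transformed into their own canonical
    frames, so the first anchors coincide at the origin and the anchor
    planes align.  The summary records each anchor pair's residual
    distance after the transform, the before/after anchor coordinates,
    and residuals for any extra matched pairs that were not used as
    anchors.
    """
    t_frame = canonical_frame(*(at.coord for at in t_anchors))
    g_frame = canonical_frame(*(at.coord for at in g_anchors))
    t_out = t_frame.transform_structure(template)
    g_out = g_frame.transform_structure(target)

    summary: dict = {"anchor_pairs": [], "extra_pairs": []}
    for ta, ga in zip(t_anchors, g_anchors):
        ta_after = t_frame.apply(ta.coord)
        ga_after = g_frame.apply(ga.coord)
        summary["anchor_pairs"].append(
            {
                "template_atom": ta.name, "target_atom": ga.name,
                "template_before": ta.coord.tolist(),
                "target_before": ga.coord.tolist(),
                "template_after": ta_after.tolist(),
                "target_after": ga_after.tolist(),
                "residual": float(np.linalg.norm(ta_after - ga_after)),
            }
        )
    for ta, ga in extra_pairs or []:
        residual = float(
            np.linalg.norm(t_frame.apply(ta.coord) - g_frame.apply(ga.coord))
        )
        summary["extra_pairs"].append(
            {"template_atom": ta.name, "target_atom": ga.name, "residual": residual}
        )
    return t_out, g_out, summary


@dataclass(frozen=True)
class NeighborRow:
    distance: float
    residue_label: str
    atom_name: str
    is_water: bool
    is_center_residue: bool
    is_hydrogen: bool


@dataclass
class NeighborReport:
    """Atoms around a center, ascending by distance; the center itself is
    listed at distance 0.  ``truncated`` marks a list cut at the first
    water."""

    center_label: str
    center_atom: str
    radius: float
    rows: list[NeighborRow]
    truncated: bool = False

    def foreign_heavy_count(self, clearance_radius: float) -> int:
        """Heavy atoms from residues other than the center's own (waters
        excluded) within the clearance radius."""
        return sum(
            1
            for r in self.rows
            if r.distance <= clearance_radius
            and not r.is_center_residue
            and not r.is_water
            and not r.is_hydrogen
        )


def neighbor_report(
    s: Structure,
    center: tuple[str | None, int, str],
    radius: float,
    stop_at_water: bool = True,
    include_hydrogens: bool = False,
) -> NeighborReport:
    """Sorted steric environment of an atom.

    ``center`` is ``(chain, residue number, atom name)``.  Atoms within
    ``radius`` are listed ascending by distance (ties broken by residue
    number then atom name).  With ``stop_at_water`` the list is truncated
    immediately after the first water encountered, mirroring how active
    sites are usually inspected: once bulk solvent appears, the cavity is
    open.  Hydrogens are skipped unless requested.
    """
    chain, number, atom_name = center
    center_res = s.residue(chain, number)
    center_atom = center_res.atom(atom_name)

    entries: list[tuple[Residue, Atom]] = [
        (r, a)
        for r in s.residues
        for a in r.atoms
        if include_hydrogens or not a.is_hydrogen
    ]
    coords = np.array([a.coord for _, a in entries])
    tree = cKDTree(coords)
    idx = tree.query_ball_point(center_atom.coord, r=radius)
    hits = [
        (float(np.linalg.norm(entries[i][1].coord - center_atom.coord)),
         entries[i][0], entries[i][1])
        for i in idx
    ]
    hits.sort(key=lambda t: (t[0], t[1].number, t[2].name))

    rows: list[NeighborRow] = []
    truncated = False
    for d, res, atom in hits:
        rows.append(
            NeighborRow(
                distance=d,
                residue_label=res.label,
                atom_name=atom.name,
                is_water=is_water(res),
                is_center_residue=res.address == center_res.address,
                is_hydrogen=atom.is_hydrogen,
            )
        )
        if stop_at_water and is_water(res):
            truncated = True
            break
    return NeighborReport(
        center_label=center_res.label,
        center_atom=atom_name,
        radius=radius,
        rows=rows,
        truncated=truncated,
    )


@dataclass
class MutationSuggestion:
    """Target residues near an unmatched template residue's reactive atom,
    each a candidate for substitution to the template residue type."""

    template_label: str
    candidates: list[tuple[str, float, str]]  # (target label, distance Å, e.g. "Asn35Asp")


def suggest_mutations(
    template: Structure,
    target: Structure,
    matched_target_residues: list[tuple[str | None, int]],
    unmatched_template: list[tuple[tuple[str | None, int], str]],
    cutoff: float = 5.0,
) -> list[MutationSuggestion]:
    """Propose target mutations that would recreate missing motif residues.

    Both structures must already be in the common (superposed) frame.
    ``unmatched_template`` lists ``((chain, resnum), reactive atom name)``
    for template motif residues without a counterpart in the target.  For
    each, target residues (waters and already-matched residues excluded)
    with any heavy atom within ``cutoff`` Å of the reactive atom are
    returned closest-first; the proposed substitution replaces the target
    residue by the template residue's type.
    """
    matched = set()
    for chain, number in matched_target_residues:
        res = target.residue(chain, number)
        matched.add(res.address)

    out: list[MutationSuggestion] = []
    for (chain, number), atom_name in unmatched_template:
        t_res = template.residue(chain, number)
        t_atom = t_res.atom(atom_name)
        cands = []
        for r in target.residues:
            if r.address in matched or is_water(r):
                continue
            dmin = min(
                (float(np.linalg.norm(a.coord - t_atom.coord))
                 for a in r.atoms if not a.is_hydrogen),
                default=np.inf,
            )
            if dmin <= cutoff:
                new_name = t_res.label[:3]
                sub = f"{r.label}{new_name}"
                cands.append((r.label, dmin, sub))
        cands.sort(key=lambda t: t[1])
        out.append(
            MutationSuggestion(template_label=t_res.label, candidates=cands)
        )
    return out


def steric_obstruction_compare(
    reports: list[NeighborReport], clearance_radius: float = 3.0
) -> list[dict]:
    """Compare steric environments around cognate catalytic atoms.

    For each report, counts heavy atoms from residues other than the
    center's own (waters excluded) within the clearance radius; a center
    with any such atom is flagged obstructed.
    """
    table = []
    for rep in reports:
        count = rep.foreign_heavy_count(clearance_radius)
        table.append(
            {
                "center": f"{rep.center_label}/{rep.center_atom}",
                "foreign_heavy_atoms": count,
                "obstructed": count > 0,
            }
        )
    return table
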