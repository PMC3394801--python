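"""Congruence matching of partial motifs in target structures.

A candidate match assigns one target residue (with its reactive atom) to
each motif position, allowed residue types only, all residues distinct.
Spatial congruence is measured by the deviation of each target pairwise
distance from the template's reference (reference minus target, Å);
electrostatic congruence by the deviation of pairwise potential
differences (kT/e).  Candidates with any |Δd| above the distance window
are pruned during search.

The match score is the mean normalized deviation over the k(k−1)/2 pairs

    score = (1/P) Σ [ w_d |Δd| / d_ref + w_pd |ΔPD| / max(|PD_ref|, floor) ]

so 0 means perfect congruence and the distance and potential terms are
dimensionless and weighable.  Per-target scores over the whole size-k
library are averaged into the DScore (unmatched motifs contribute a
penalty); lower is better, and DScores are only ever compared within one
motif size k.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .motifs import PartialMotif
from .structio import Atom, Residue, Structure

__all__ = [
    "ScanConfig",
    "MatchResult",
    "score_match",
    "find_matches",
    "brute_force_matches",
    "dscore",
    "rank_targets",
]


@dataclass(frozen=True)
class ScanConfig:
    """Search and scoring controls.

    distance_window : Å; candidates with any pairwise |Δd| above it are
        pruned.  The default 2.5 Å is wide enough to keep loose but
        plausible sites.
    pd_floor : kT/e; reference PDs below it in magnitude are normalized
        by the floor instead, so near-zero references do not blow up the
        electrostatic term.
    """

    distance_window: float = 2.5
    d_weight: float = 1.0
    pd_weight: float = 1.0
    pd_floor: float = 10.0
    max_results: int = 25
    use_potentials: bool = False

    def __post_init__(self) -> None:
        if self.distance_window <= 0:
            raise ValueError("distance window must be positive")
        if self.d_weight < 0 or self.pd_weight < 0:
            raise ValueError("weights must be non-negative")
        if self.d_weight == 0 and self.pd_weight == 0:
            raise ValueError("at least one weight must be positive")


@dataclass
class MatchResult:
    """One candidate assignment with its per-pair deviations and score."""

    motif: PartialMotif
    assignment: tuple[tuple[Residue, Atom], ...]
    pair_dev_d: dict[tuple[int, int], float]        # reference − target, Å
    pair_dev_pd: dict[tuple[int, int], float]       # reference − target, kT/e
    score: float = 0.0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r, _ in self.assignment)


def score_match(m: MatchResult, cfg: ScanConfig) -> float:
    """Mean normalized deviation over all pairs; 0 iff perfect congruence."""
    pairs = list(m.pair_dev_d)
    total = 0.0
    for ij in pairs:
        total += cfg.d_weight * abs(m.pair_dev_d[ij]) / m.motif.distance(*ij)
        if cfg.use_potentials:
            ref_pd = m.motif.pd(*ij)
            total += (
                cfg.pd_weight
                * abs(m.pair_dev_pd[ij])
                / max(abs(ref_pd), cfg.pd_floor)
            )
    return total / len(pairs)


def _candidate_pool(pm: PartialMotif, target: Structure, use_potentials: bool):
    """Per position: list of (residue, reactive atom) with allowed type and
    the mapped atom present."""
    pools = []
    for pos in pm.positions:
        pool = []
        for r in target.residues:
            atom_name = pos.allowed_atoms.get(r.name.upper())
            if atom_name is None or not r.has_atom(atom_name):
                continue
            atom = r.atom(atom_name)
            if use_potentials and atom.potential is None:
                raise ValueError(
                    f"potentials required but unassigned on {r.label}/{atom_name}"
                )
            pool.append((r, atom))
        pools.append(pool)
    return pools


def _finish(pm, assignment, cfg) -> MatchResult:
    k = len(assignment)
    dev_d, dev_pd = {}, {}
    for i in range(k):
        for j in range(i + 1, k):
            d_t = float(np.linalg.norm(assignment[i][1].coord - assignment[j][1].coord))
            dev_d[(i, j)] = pm.distance(i, j) - d_t
            if cfg.use_potentials:
                pd_t = assignment[i][1].potential - assignment[j][1].potential
                dev_pd[(i, j)] = pm.pd(i, j) - pd_t
    m = MatchResult(motif=pm, assignment=tuple(assignment),
                    pair_dev_d=dev_d, pair_dev_pd=dev_pd)
    m.score = score_match(m, cfg)
    return m


def find_matches(pm: PartialMotif, target: Structure,
                 cfg: ScanConfig = ScanConfig()) -> list[MatchResult]:
    """All congruent matches of a partial motif in a target, best first.

    Builds tuples position by position, checking every new reactive atom
    against all previously placed ones (incremental distance pruning), so
    the search stays polynomial on real structures; the brute-force
    enumerator :func:`brute_force_matches` is the reference behaviour.
    Returns an empty list when no candidate survives.
    """
    if pm.has_pds is False and cfg.use_potentials:
        raise ValueError("config requires potentials but motif has no reference PDs")
    pools = _candidate_pool(pm, target, cfg.use_potentials)
    if any(not p for p in pools):
        return []

    results: list[MatchResult] = []
    k = pm.k
    assignment: list[tuple[Residue, Atom]] = []
    used: set[tuple[str, int, str]] = set()

    def extend(pos_idx: int) -> None:
        if pos_idx == k:
            results.append(_finish(pm, assignment, cfg))
            return
        for r, atom in pools[pos_idx]:
            if r.address in used:
                continue
            ok = True
            for prev_idx, (_, prev_atom) in enumerate(assignment):
                d_t = float(np.linalg.norm(atom.coord - prev_atom.coord))
                if abs(pm.distance(prev_idx, pos_idx) - d_t) > cfg.distance_window:
                    ok = False
                    break
            if ok:
                assignment.append((r, atom))
                used.add(r.address)
                extend(pos_idx + 1)
                assignment.pop()
                used.discard(r.address)

    extend(0)
    results.sort(key=lambda m: (m.score, m.labels))
    return results[: cfg.max_results]


def brute_force_matches(pm: PartialMotif, target: Structure,
                        cfg: ScanConfig = ScanConfig()) -> list[MatchResult]:
    """Exhaustive reference enumeration over all ordered residue tuples.

    Exponential in k; intended as an oracle on small structures.
    """
    results = []
    for combo in permutations(target.residues, pm.k):
        assignment = []
        for pos_idx, r in enumerate(combo):
            atom_name = pm.positions[pos_idx].allowed_atoms.get(r.name.upper())
            if atom_name is None or not r.has_atom(atom_name):
                assignment = None
                break
            assignment.append((r, r.atom(atom_name)))
        if assignment is None:
            continue
        m = _finish(pm, assignment, cfg)
        if all(abs(v) <= cfg.distance_window for v in m.pair_dev_d.values()):
            results.append(m)
    results.sort(key=lambda m: (m.score, m.labels))
    return results[: cfg.max_results]


def dscore(per_motif_results: list[tuple[PartialMotif, MatchResult | None]],
           penalty: float = 1.0) -> float:
    """Cumulative per-protein score: mean over the motif library of the
    best match score, with ``penalty`` for motifs that found no match."""
    if not per_motif_results:
        raise ValueError("empty motif library")
    vals = [best.score if best is not None else penalty
            for _, best in per_motif_results]
    return float(np.mean(vals))


def rank_targets(
    targets: list[Structure],
    library: list[PartialMotif],
    cfg: ScanConfig = ScanConfig(),
    penalty: float = 1.0,
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score every target against the whole size-k library and rank.

    Returns a DataFrame (structure_id, description, dscore) sorted by
    ascending DScore, ties broken by structure id.
    """
    if not targets:
        raise ValueError("at least one target structure required")
    descriptions = descriptions or {}
    rows = []
    for t in targets:
        per_motif = []
        for pm in library:
            found = find_matches(pm, t, cfg)
            per_motif.append((pm, found[0] if found else None))
        rows.append(
            {
                "structure_id": t.id,
                "description": descriptions.get(t.id, ""),
                "dscore": dscore(per_motif, penalty),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["dscore", "structure_id"], kind="mergesort"
    ).reset_index(drop=True)
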