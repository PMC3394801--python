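# Methods

## Model

`decaaf` treats an enzyme's catalytic machinery as a small set of
*reactive atoms* — one functionally decisive atom per active-site
residue — and asks whether another structure contains a residue tuple
whose reactive atoms reproduce the template's pairwise geometry and,
optionally, its pairwise electrostatic potential differences. Both
descriptors are rigid-motion invariant, so matching needs no prior
structural alignment; superposition comes *after* a match is found, to
place unmatched template residues inside the target site.

The default reactive-atom map is Ser→OG, Thr→OG1, Tyr→OH, Cys→SG,
His→ND1, Lys→NZ, Arg→NH1, Asp→OD1, Glu→OE1, Asn→OD1, Gln→OE1, Gly→N,
Ala→N, with CA as fallback so every residue stays addressable. His uses
the ND1 tautomer nitrogen by default; NE2 can be selected per position
with an atom override. Residue addressing uses author numbering with
insertion codes, exactly as deposited; no renumbering.

## Matching and scoring

Candidate tuples are built position by position from residues whose
type is in the position's allowed set (and which actually contain the
mapped atom — truncated side chains are silently skipped as
unmatchable). Each newly placed atom is checked against all previously
placed ones: a candidate with any pairwise |Δd| above the distance
window (default 2.5 Å) is pruned before extension. This keeps the
search polynomial in practice; an exhaustive enumerator
(`brute_force_matches`) is kept as the reference behaviour and the test
oracle.

The score of a surviving candidate is the mean normalized deviation

    score = (1/P) Σ_pairs [ w_d |Δd| / d_ref + w_pd |ΔPD| / max(|PD_ref|, floor) ]

with P = k(k−1)/2 pairs, defaults w_d = w_pd = 1 and PD floor 10 kT/e.
Design rationale: the score is 0 exactly at perfect congruence,
dimensionless, linear in each deviation, and the floor prevents a
near-zero reference PD from dominating. Deviations follow the
reference-minus-target sign convention; PDs are compared as signed
ordered differences (earlier motif position minus later), not absolute
values. Published score magnitudes from the original congruence
scorer are not reproducible (its formula is defined in prior work and
tuned to a different target set), so correctness here rests on
property guarantees: zero at self-match, monotonicity in each
deviation, and agreement with the brute-force oracle.

The per-protein DScore for motif size k is the mean of best per-motif
scores over the full C(N, k) library, with a penalty (default 1.0) for
motifs with no surviving match. Scores for different k are never
merged: there is no principled exchange rate between a tight 3-motif
and a loose 5-motif, so rankings are reported per k.

## Electrostatics

Potentials are values in kT/e attached to atoms, from one of three
sources: a Poisson–Boltzmann solver grid in OpenDX format (trilinearly
interpolated at atom centers — sampling at the atom center rather than
over a shell is an assumption), a per-atom TSV table, or a built-in
screened-Coulomb fallback over the structure's own partial charges
(PQR input): V(x) = Σ_i q_i e^{−r_i/λ}/(ε r_i), with defaults ε = 2
(solute dielectric), T = 298 K, no screening (zero ionic strength) and
a 0.5 Å distance clamp against bonded-neighbor singularities. The
conversion to kT/e is computed from physical constants at the
configured temperature (≈ 560.7 kT/e per unit charge per Å at 298 K in
vacuum). Solving the Poisson–Boltzmann equation itself is out of
scope — the fallback exists so the whole pipeline is testable
self-contained, not as a replacement for a solver; solver-grade numbers
should come in through the grid or table sources.

## Superposition

The superposition is the exact 3-anchor canonical-frame construction:
each structure is moved so its first anchor is at the origin, its
second on the +X axis, its third in the Z = 0 plane with Y > 0. The
rotation rows are the Gram–Schmidt frame (e1 along anchor1→anchor2, e2
the in-plane component of anchor1→anchor3, e3 = e1 × e2), hence always
proper — the construction cannot reflect. Anchors closer to collinear
than a triangle height of 1e-6 Å are rejected. A least-squares
(Kabsch) fit is deliberately not used: the method anchors the frame on
the matched catalytic atoms alone, and reports residual distances of
any additional matched pairs so geometric strain (including the
enantiomeric-site ambiguity that pairwise distances cannot resolve) is
visible rather than averaged away.

Mutation suggestion takes the superposed pair, and for each unmatched
template residue's reactive atom lists target residues (waters and
already-matched residues excluded) with any heavy atom within a cutoff
(default 5 Å, measured reactive-atom-to-nearest-heavy-atom), sorted
closest-first; the proposed substitution renames the target residue to
the template type (Asn35 near an unmatched Asp → Asn35Asp).

Neighbor reports list atoms around a center ascending by distance
(ties broken by residue number then atom name), hydrogens excluded by
default, optionally truncated immediately after the first water: once
bulk solvent appears the cavity is open, so deeper atoms say nothing
about obstruction. Steric comparison counts heavy atoms from *other*
residues within a clearance radius (default 3 Å) and flags any center
with a nonzero count as obstructed.

## Synthetic data

The fixture generator covers three needs. (1) Anchor fixtures carry
the published reactive-atom coordinates of the elastase (1B0F) and
P14A (1CFE) partial match, plus minimal backbone stubs so the residues
survive PDB round-trips; they make the worked superposition example
reproducible offline. (2) `plant_motif` embeds a copy of a template's
reactive-atom geometry (reconstructed from the reference distances by
classical multidimensional scaling), perturbed by isotropic Gaussian
noise of chosen σ, among decoy residues drawn uniformly from the 20
standard types at ≈ 0.01 residues/Å³ — dense enough to produce
near-miss candidates — under a random rigid motion, and records the
ground-truth assignment. Recovery studies use the four-residue
extended elastase scaffold (Ser195, His57, Ser214, Gly193) built from
its published pairwise distances, whose well-separated distances make
the best assignment unique; the bare Ser-His-Ser triangle is nearly
isoceles, so exact assignment recovery under noise is intrinsically
ambiguous there. (3) A synthetic reconstruction of the Class A
β-lactamase deacylation-base site places the Glu166 atoms and the
first water at their published distances from OE1; it exercises
ordering, water truncation and clearance counting, but its
*directions* are invented — it validates the report machinery, not the
deposited 1E25 geometry.

None of the generators attempt physical realism (no backbone
continuity, sterics or rotamers). Passing tests therefore demonstrate
correctness of the matching, scoring and frame arithmetic under known
ground truth, not performance on real proteomes, where side-chain
flexibility, missing atoms and solvent structure add noise the
generator does not model.

## Problem sizes and determinism

Tests and the acceptance script run on structures of ≤ ~35 residues,
100-replicate recovery studies at σ ∈ {0, 0.3} Å plus a smaller study
at σ = 1.0 Å, and 1000-trial rigid-motion invariance checks; the whole
suite completes in seconds. All randomness flows through seeded
`numpy.random.Generator` instances; fixed seed ⇒ identical structures,
identical outputs. CLI tables carry a configuration header and no
timestamps, so identical inputs give byte-identical files.

## Known limitations

- Matching is combinatorial in k for pathological inputs (many
  residues of one type within the window); the incremental pruning,
  not an asymptotic guarantee, keeps it fast.
- Pairwise-distance congruence cannot distinguish a site from its
  mirror image; only the reported residuals of extra matched pairs
  reveal it.
- The Coulomb fallback ignores solvent screening geometry; its PDs are
  self-consistent but not comparable in magnitude to solver-derived
  ones.
- Grid sources must cover every atom; atoms outside the lattice are an
  error rather than an extrapolation.
- mmCIF input, structure repair, hydrogen placement and automatic
  active-site detection are out of scope; template residues are user
  input.
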