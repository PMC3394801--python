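# decaaf

Directed-evolution target selection by spatial and electrostatic
congruence of partial active-site motifs.

## The problem

Endowing a protein with a new enzymatic activity is far more likely to
succeed when the protein already carries a partial copy of the required
catalytic scaffold. Given a *template* enzyme with known structure and
active-site residues (for example human neutrophil elastase, whose
scaffold is the catalytic triad plus oxyanion-hole residues Ser195,
His57, Asp102, Ser214, Gly193), `decaaf`:

1. builds a **template motif**: one *reactive atom* per active-site
   residue (Ser/OG, His/ND1, Gly/backbone N, ...) with all pairwise
   distances `d_ref` (Å) and, optionally, pairwise electrostatic
   potential differences `PD_ref` (kT/e);
2. enumerates the **partial-motif library** — all order-preserved
   k-subsets, `C(N, k)` motifs per size k ≥ 3;
3. **scans** candidate structures for congruent residue tuples and ranks
   them by a cumulative per-protein score (the *DScore*, lower = more
   congruent);
4. **superposes** template and target on the best 3-atom partial match
   with an exact canonical-frame construction (no least-squares), so
   that unmatched template residues land inside the target's site; and
5. **proposes mutations**: target residues spatially close to an
   unmatched template residue's reactive atom become substitution
   candidates (e.g. Asn35Asp), while a neighbor report around catalytic
   atoms diagnoses steric obstruction of the site.

A match of a k-motif assigns distinct target residues (of allowed types;
stereochemical equivalences such as Ser↔Tyr or Gly↔Ala are opt-in per
position) to the motif positions. With per-pair deviations
`Δd = d_ref − d_target` and `ΔPD = PD_ref − PD_target`, the match score is

```
score = (1/P) Σ_pairs [ w_d·|Δd|/d_ref + w_pd·|ΔPD|/max(|PD_ref|, floor) ],   P = k(k−1)/2
```

which is 0 exactly at perfect congruence. The DScore of a protein is the
mean of its best per-motif scores over the size-k library (a penalty is
charged for motifs with no surviving match); DScores are only compared
within one k.

The canonical frame maps anchor 1 to the origin, anchor 2 to the +X
axis, and anchor 3 into the Z = 0 plane with Y > 0, by a proper rotation
(chirality is never flipped).

## Worked example

Superpose the elastase anchors on the predicted scaffold of the tomato
pathogenesis-related protein P14A:

```
decaaf fixtures --which hne_1b0f  --out hne.pdb
decaaf fixtures --which p14a_1cfe --out p14a.pdb
cat > pairs.yaml <<EOF
- {template: Ser195/OG, target: Ser49/OG}
- {template: His57/ND1, target: His48/ND1}
- {template: Ser214/OG, target: Tyr36/OH}
EOF
decaaf superpose --template hne.pdb --target p14a.pdb --pairs pairs.yaml --out-prefix run
cat run.summary.tsv
```

prints the before/after coordinate block

```
role      atom       before_x before_y before_z after_x after_y after_z residual
template  Ser195/OG  64.4     57.0     53.8     0.0     0.0     0.0     0.0
template  His57/ND1  63.3     54.8     58.2     5.0     0.0     -0.0    0.1
template  Ser214/OG  63.6     50.6     56.1     5.0     4.7     -0.0    0.3
target    Ser49/OG   8.8      -6.3     -4.8     0.0     0.0     0.0     0.0
target    His48/ND1  9.2      -2.4     -1.8     4.9     -0.0    0.0     0.1
target    Tyr36/OH   13.7     -1.6     -3.7     4.8     4.9     0.0     0.3
```

Both anchor triples land on the same plane with their first atoms
coincident; the residual column shows how closely the two scaffolds
overlap (0.1–0.3 Å here — a near-congruent partial match). Scanning and
mutation suggestion work the same way through `decaaf scan` and
`decaaf suggest`; `decaaf neighbors` prints the sorted steric
environment of a catalytic atom, truncated at the first water.

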