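"""Canonical-frame superposition, neighbor reports, mutation proposals."""

import numpy as np
import pytest

from decaaf import (
    canonical_frame,
    make_glu166_site_fixture,
    neighbor_report,
    steric_obstruction_compare,
    suggest_mutations,
    superpose_pair,
)
from decaaf.structio import Atom, Residue, Structure
from decaaf.superpose import GeometryError


def random_rigid(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-20, 20, size=3)


def anchors_of(s, specs):
    return tuple(s.residue(None, n).atom(a) for n, a in specs)


HNE_SPECS = [(195, "OG"), (57, "ND1"), (214, "OG")]
CFE_SPECS = [(49, "OG"), (48, "ND1"), (36, "OH")]


def test_canonical_frame_axioms(hne):
    a, b, c = (at.coord for at in anchors_of(hne, HNE_SPECS))
    t = canonical_frame(a, b, c)
    np.testing.assert_allclose(t.apply(a), 0.0, atol=1e-12)
    tb, tc = t.apply(b), t.apply(c)
    assert tb[0] > 0 and abs(tb[1]) < 1e-12 and abs(tb[2]) < 1e-12
    assert abs(tc[2]) < 1e-12 and tc[1] > 0
    r = t.rotation
    np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "specs,fixture_name,expected",
    [
        (HNE_SPECS, "hne",
         {195: (0.0, 0.0, 0.0), 57: (5.0, 0.0, 0.0), 214: (5.0, 4.7, 0.0)}),
        (CFE_SPECS, "p14a",
         {49: (0.0, 0.0, 0.0), 48: (4.9, 0.0, 0.0), 36: (4.7, 5.0, 0.0)}),
    ],
)
def test_canonical_coordinates_match_published_table(specs, fixture_name,
                                                     expected, request):
    """Both anchor triples land on their published after-coordinates
    (0.1 Å; the inputs themselves are printed at 0.1 Å precision)."""
    s = request.getfixturevalue(fixture_name)
    atoms = anchors_of(s, specs)
    t = canonical_frame(*(at.coord for at in atoms))
    for (num, _), at in zip(specs, atoms):
        got = t.apply(at.coord)
        np.testing.assert_allclose(got, expected[num], atol=0.1)


def test_already_canonical_anchors_give_identity():
    t = canonical_frame((0, 0, 0), (2, 0, 0), (1, 1, 0))
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t.shift, 0.0, atol=1e-12)


def test_canonical_frame_invariant_under_rigid_motion(hne):
    coords = [at.coord for at in anchors_of(hne, HNE_SPECS)]
    base = canonical_frame(*coords)
    ref = [base.apply(c) for c in coords]
    rng = np.random.default_rng(42)
    for _ in range(200):
        rot, trans = random_rigid(rng)
        moved = [rot @ c + trans for c in coords]
        t = canonical_frame(*moved)
        for r, m in zip(ref, moved):
            assert np.linalg.norm(t.apply(m) - r) < 1e-9


def test_canonical_frame_rigid_and_chiral():
    rng = np.random.default_rng(7)
    pts = rng.uniform(-10, 10, size=(4, 3))   # a test tetrahedron
    t = canonical_frame(pts[0], pts[1], pts[2])
    out = t.apply(pts)
    # pairwise distances preserved
    for i in range(4):
        for j in range(i + 1, 4):
            assert np.linalg.norm(out[i] - out[j]) == pytest.approx(
                np.linalg.norm(pts[i] - pts[j]), abs=1e-9)
    # signed volume (chirality) preserved: no reflection
    def vol(p):
        return np.linalg.det(np.array([p[1] - p[0], p[2] - p[0], p[3] - p[0]]))
    assert np.sign(vol(out)) == np.sign(vol(pts))
    assert vol(out) == pytest.approx(vol(pts), rel=1e-9)


@pytest.mark.parametrize(
    "a,b,c",
    [((0, 0, 0), (0, 0, 0), (1, 1, 0)),          # coincident
     ((0, 0, 0), (1, 0, 0), (2, 0, 0)),          # collinear
     ((0, 0, 0), (1, 0, 0), (0.5, 1e-8, 0))],    # nearly collinear
)
def test_degenerate_anchors_rejected(a, b, c):
    with pytest.raises(GeometryError):
        canonical_frame(a, b, c)


def test_superpose_pair_published_anchor_frames(hne, p14a):
    t_out, g_out, summary = superpose_pair(
        hne, anchors_of(hne, HNE_SPECS), p14a, anchors_of(p14a, CFE_SPECS)
    )
    # first anchors coincide at the origin
    np.testing.assert_allclose(t_out.residue(None, 195).atom("OG").coord, 0,
                               atol=1e-12)
    np.testing.assert_allclose(g_out.residue(None, 49).atom("OG").coord, 0,
                               atol=1e-12)
    assert summary["anchor_pairs"][0]["residual"] == pytest.approx(0.0, abs=1e-12)
    after = summary["anchor_pairs"][2]["target_after"]
    np.testing.assert_allclose(after, [4.7, 5.0, 0.0], atol=0.1)


def test_superpose_with_itself_coincides(hne):
    anchors = anchors_of(hne, HNE_SPECS)
    t_out, g_out, summary = superpose_pair(hne, anchors, hne, anchors)
    for a0, a1 in zip(t_out.atoms, g_out.atoms):
        np.testing.assert_allclose(a0.coord, a1.coord, atol=1e-12)
    assert all(p["residual"] == pytest.approx(0.0, abs=1e-12)
               for p in summary["anchor_pairs"])


def test_extra_matched_pair_residual_reported(hne):
    """A fourth matched pair not used as an anchor superposes closely when
    the target is a rigidly moved copy of the template."""
    rng = np.random.default_rng(1)
    rot, trans = random_rigid(rng)
    moved = hne.copy()
    for a in moved.atoms:
        a.coord = rot @ a.coord + trans
    extra = (hne.residue(None, 195).atom("CA"), moved.residue(None, 195).atom("CA"))
    _, _, summary = superpose_pair(
        hne, anchors_of(hne, HNE_SPECS), moved, anchors_of(moved, HNE_SPECS),
        extra_pairs=[extra],
    )
    assert summary["extra_pairs"][0]["residual"] < 1e-9


def _toy_structure(rows):
    """rows: (resnum, resname, atomname, coord)."""
    residues = {}
    for i, (num, resname, atom, coord) in enumerate(rows):
        res = residues.setdefault(num, Residue(chain_id="A", number=num,
                                               name=resname))
        res.atoms.append(Atom(serial=i + 1, name=atom,
                              element=atom[0], coord=np.asarray(coord, float)))
    return Structure(id="toy", residues=list(residues.values()))


def test_neighbor_report_radius_and_sorting():
    s = _toy_structure([
        (1, "GLU", "OE1", (0, 0, 0)),
        (2, "ALA", "CB", (2, 0, 0)),
        (3, "GLY", "CA", (4, 0, 0)),
    ])
    rep = neighbor_report(s, ("A", 1, "OE1"), radius=3.5, stop_at_water=True)
    assert [(r.residue_label, r.atom_name) for r in rep.rows] \
        == [("Glu1", "OE1"), ("Ala2", "CB")]
    assert rep.rows[0].distance == 0.0
    assert not rep.truncated


def test_neighbor_report_truncates_after_first_water():
    s = _toy_structure([
        (1, "GLU", "OE1", (0, 0, 0)),
        (2, "ALA", "CB", (1, 0, 0)),
        (100, "HOH", "O", (2, 0, 0)),
        (3, "GLY", "CA", (3, 0, 0)),
    ])
    rep = neighbor_report(s, ("A", 1, "OE1"), radius=5.0, stop_at_water=True)
    assert rep.truncated
    assert rep.rows[-1].residue_label == "HOH100"
    assert len(rep.rows) == 3    # center, CB, then the water ends the list
    full = neighbor_report(s, ("A", 1, "OE1"), radius=5.0, stop_at_water=False)
    assert not full.truncated
    # the truncated report is a prefix of the full one
    assert [(r.residue_label, r.atom_name) for r in full.rows[:3]] \
        == [(r.residue_label, r.atom_name) for r in rep.rows]
    assert len(full.rows) == 4


def test_neighbor_report_ties_broken_by_number_then_atom():
    s = _toy_structure([
        (1, "GLU", "OE1", (0, 0, 0)),
        (5, "PRO", "CA", (1.6, 0, 0)),
        (5, "PRO", "C", (0, 1.6, 0)),
        (4, "LEU", "CB", (0, 0, 1.6)),
    ])
    rep = neighbor_report(s, ("A", 1, "OE1"), radius=2.0)
    assert [(r.residue_label, r.atom_name) for r in rep.rows[1:]] \
        == [("Leu4", "CB"), ("Pro5", "C"), ("Pro5", "CA")]


def test_glu166_site_report_matches_published_environment():
    """The synthetic β-lactamase site reproduces the published steric
    picture: nearest heavy atom Glu166/CD at 1.3 Å, the list ends at the
    first water (3.1 Å), and no foreign heavy atom lies within 3 Å."""
    s = make_glu166_site_fixture()
    rep = neighbor_report(s, ("A", 166, "OE1"), radius=3.5, stop_at_water=True)
    rows = [(round(r.distance, 1), r.residue_label, r.atom_name) for r in rep.rows]
    assert rows == [
        (0.0, "Glu166", "OE1"), (1.3, "Glu166", "CD"), (2.2, "Glu166", "OE2"),
        (2.4, "Glu166", "CG"), (2.7, "Glu166", "CB"), (3.0, "Glu166", "CA"),
        (3.1, "HOH2076", "O"),
    ]
    assert rep.truncated
    assert rep.foreign_heavy_count(3.0) == 0


def test_obstruction_comparison_flags_crowded_center():
    clear = neighbor_report(make_glu166_site_fixture(), ("A", 166, "OE1"), 3.5)
    crowded_s = _toy_structure([
        (158, "GLU", "OE1", (0, 0, 0)),
        (159, "PRO", "C", (1.6, 0, 0)),       # foreign atoms inside 3 Å
        (160, "ASP", "N", (0, 2.6, 0)),
    ])
    crowded = neighbor_report(crowded_s, ("A", 158, "OE1"), 3.5)
    table = steric_obstruction_compare([clear, crowded], clearance_radius=3.0)
    assert table[0]["obstructed"] is False
    assert table[1] == {"center": "Glu158/OE1", "foreign_heavy_atoms": 2,
                        "obstructed": True}
    empty = neighbor_report(_toy_structure([(1, "GLU", "OE1", (0, 0, 0))]),
                            ("A", 1, "OE1"), 3.5)
    assert steric_obstruction_compare([empty], 3.0)[0]["obstructed"] is False


def test_suggest_mutations_planted_candidate(hne):
    """A target residue placed exactly at the unmatched template atom is
    the sole top candidate at distance ~0."""
    asp_pos = np.array([60.0, 55.0, 50.0])
    template = _toy_structure([(102, "ASP", "OD1", asp_pos)])
    target = _toy_structure([
        (35, "ASN", "OD1", asp_pos),              # planted right on top
        (39, "SER", "OG", asp_pos + [3.0, 0, 0]),
        (49, "SER", "OG", asp_pos + [1.0, 0, 0]),  # matched → excluded
        (200, "HOH", "O", asp_pos + [0.5, 0, 0]),  # water → excluded
        (60, "LEU", "CD1", asp_pos + [30.0, 0, 0]),  # beyond cutoff
    ])
    out = suggest_mutations(template, target,
                            matched_target_residues=[(None, 49)],
                            unmatched_template=[((None, 102), "OD1")],
                            cutoff=5.0)
    assert len(out) == 1
    sug = out[0]
    assert sug.template_label == "Asp102"
    assert [c[0] for c in sug.candidates] == ["Asn35", "Ser39"]
    assert sug.candidates[0][1] == pytest.approx(0.0, abs=1e-12)
    assert [c[2] for c in sug.candidates] == ["Asn35Asp", "Ser39Asp"]


def test_suggest_mutations_empty_unmatched_gives_empty():
    s = _toy_structure([(1, "SER", "OG", (0, 0, 0))])
    assert suggest_mutations(s, s, [], [], cutoff=5.0) == []


def test_suggest_mutations_invariant_to_common_rigid_motion():
    template = _toy_structure([(102, "ASP", "OD1", (1.0, 2.0, 3.0))])
    target = _toy_structure([(35, "ASN", "OD1", (2.0, 2.0, 3.0))])
    base = suggest_mutations(template, target, [], [((None, 102), "OD1")], 5.0)
    rng = np.random.default_rng(3)
    rot, trans = random_rigid(rng)
    for s in (template, target):
        for a in s.atoms:
            a.coord = rot @ a.coord + trans
    moved = suggest_mutations(template, target, [], [((None, 102), "OD1")], 5.0)
    assert moved[0].candidates[0][0] == base[0].candidates[0][0]
    assert moved[0].candidates[0][1] == pytest.approx(base[0].candidates[0][1],
                                                      abs=1e-9)
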