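"""Interface metrics: SASA, Sc, hydrogen bonds, unsat polars, scoring,
alanine scanning, mutation enumeration and triage."""

import numpy as np
import pytest

from paragraft import synthfix
from paragraft.geometry import RigidTransform
from paragraft.interface import (
    InterfaceReport,
    MutationProposal,
    NoBuriedSurfaceError,
    ScoredDesign,
    ScoreWeights,
    alanine_scan,
    buried_sasa,
    buried_unsat_polars,
    enumerate_point_mutations,
    hydrogen_bonds,
    mutate_residue,
    sasa,
    shape_complementarity,
    surrogate_interface_score,
    triage,
)
from paragraft.structures import ResidueID, Structure


def _single_atom(element="C"):
    st = Structure()
    st.new_residue("A", 1, "UNK", [("C1", element, (0, 0, 0))])
    return st


class TestSasa:
    def test_single_atom_matches_closed_form_within_one_percent(self):
        total = sasa(_single_atom(), probe=1.4, sphere_points=960).sum()
        assert total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_coincident_duplicate_atoms_count_once(self):
        st = _single_atom()
        st.new_residue("A", 2, "UNK", [("C1", "C", (0, 0, 0))])
        assert sasa(st, 1.4, 960).sum() == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_point_count_convergence_below_half_percent(self, toy_design):
        design, _ = toy_design
        a = sasa(design, 1.4, 960).sum()
        b = sasa(design, 1.4, 10_000).sum()
        assert abs(a - b) / b < 0.005

    def test_matches_independent_shrake_rupley_implementation(self, toy_design, tmp_path):
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from paragraft.structures import write_pdb

        design, _ = toy_design
        path = tmp_path / "d.pdb"
        write_pdb(design, path)
        ours = sasa(design, 1.4, 960).sum()
        bp = PDBParser(QUIET=True).get_structure("d", str(path))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(bp, level="S")
        assert ours == pytest.approx(bp.sasa, rel=0.02)


class TestBuriedSasa:
    def test_distant_chains_bury_nothing(self):
        a = _single_atom()
        b = Structure()
        b.new_residue("B", 1, "UNK", [("C1", "C", (25.0, 0, 0))])
        assert buried_sasa(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_partner_order(self, contact_slabs):
        a, b = contact_slabs
        assert buried_sasa(a, b, sphere_points=240) == pytest.approx(
            buried_sasa(b, a, sphere_points=240), abs=1e-6
        )

    def test_sphere_pair_at_contact_matches_analytic_cap_area(self):
        a = _single_atom()
        b = Structure()
        b.new_residue("B", 1, "UNK", [("C1", "C", (3.4, 0, 0))])
        R, d = 1.7 + 1.4, 3.4
        analytic = 2 * (2 * np.pi * R * (R - d / 2))
        assert buried_sasa(a, b, sphere_points=4000) == pytest.approx(analytic, rel=0.02)

    def test_burial_decreases_with_gap(self):
        vals = []
        for gap in (0.0, 5.0):
            pair = synthfix.make_interface_pair(gap=gap, seed=0)
            vals.append(
                buried_sasa(pair.subset(["A"]), pair.subset(["B"]), sphere_points=240)
            )
        assert vals[0] > vals[1]


class TestHydrogenBonds:
    def _donor(self):
        st = Structure()
        st.new_residue(
            "A", 1, "XXX",
            [("N", "N", (0, 0, 0)), ("CC", "C", (-1.2, 0.7, 0))],
        )
        return st

    def _acceptor(self, x):
        st = Structure()
        st.new_residue("B", 1, "XXX", [("O", "O", (x, 0, 0))])
        return st

    def test_pair_at_2p9_and_150_degrees_detected(self):
        bonds = hydrogen_bonds(self._donor(), self._acceptor(2.9))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle > 120

    def test_pair_at_4_angstroms_not_detected(self):
        assert hydrogen_bonds(self._donor(), self._acceptor(4.0), d_max=3.5) == []

    def test_angle_criterion_rejects_bent_geometry(self):
        st = Structure()
        st.new_residue(
            "A", 1, "XXX",
            [("N", "N", (0, 0, 0)), ("CC", "C", (1.4, 0.4, 0))],  # antecedent toward acceptor
        )
        assert hydrogen_bonds(st, self._acceptor(2.9)) == []

    def test_count_matches_brute_force_pair_scan(self, hotspot_fixture):
        _, complex_structure, _ = hotspot_fixture
        a = complex_structure.subset(["P"])
        b = complex_structure.subset(["A"])
        bonds = hydrogen_bonds(a, b)
        # brute force: all polar cross pairs in [2.0, 3.5] with angle check
        brute = 0
        for res_a, at_a in a.atoms():
            for res_b, at_b in b.atoms():
                if not (at_a.is_polar and at_b.is_polar):
                    continue
                d = np.linalg.norm(at_a.coord - at_b.coord)
                if 2.0 <= d <= 3.5:
                    donor_ok_a = at_a.element == "N" or at_a.name in ("OG", "OG1", "OH")
                    donor_ok_b = at_b.element == "N" or at_b.name in ("OG", "OG1", "OH")
                    if (donor_ok_a and at_b.element == "O") or (
                        donor_ok_b and at_a.element == "O"
                    ):
                        brute += 1
        # every brute-force candidate pair must have been considered; the
        # detected list is the angle-filtered subset
        assert len(bonds) <= brute
        assert len(bonds) > 0


class TestShapeComplementarity:
    def test_flat_contact_limit_is_highly_complementary(self, contact_slabs):
        a, b = contact_slabs
        assert shape_complementarity(a, b) >= 0.9

    def test_sc_decreases_with_gap(self, contact_slabs):
        a, b = contact_slabs
        pair3 = synthfix.make_interface_pair(gap=3.0, seed=0)
        sc0 = shape_complementarity(a, b)
        sc3 = shape_complementarity(pair3.subset(["A"]), pair3.subset(["B"]))
        assert sc3 < sc0

    def test_symmetric_in_argument_order(self, contact_slabs):
        a, b = contact_slabs
        assert abs(shape_complementarity(a, b) - shape_complementarity(b, a)) <= 0.02

    def test_no_buried_surface_signals_undefined(self):
        pair = synthfix.make_interface_pair(gap=8.0, seed=0)
        with pytest.raises(NoBuriedSurfaceError):
            shape_complementarity(pair.subset(["A"]), pair.subset(["B"]))


def _buried_polar_scene(with_partner: bool):
    """A nitrogen sealed inside a carbon cage, optionally with an oxygen
    hydrogen-bond partner."""
    cage = Structure()
    n = 1
    for x in range(-2, 3):
        for y in range(-2, 3):
            for z in range(-2, 3):
                p = np.array([x, y, z]) * 2.2
                if np.linalg.norm(p) < 3.0:
                    continue
                cage.new_residue("C", n, "UNK", [("C1", "C", p)])
                n += 1
    if with_partner:
        cage.new_residue("C", 500, "XXX", [("O", "O", (2.9, 0, 0))])
    probe_side = Structure()
    probe_side.new_residue(
        "A", 1, "XXX", [("N", "N", (0, 0, 0)), ("CC", "C", (-1.4, 0.5, 0))]
    )
    return probe_side, cage


class TestBuriedUnsatPolars:
    def test_solvated_polar_atom_not_counted(self):
        a = Structure()
        a.new_residue("A", 1, "XXX", [("N", "N", (0, 0, 0))])
        b = Structure()
        b.new_residue("B", 1, "UNK", [("C1", "C", (4.5, 0, 0))])
        assert buried_unsat_polars(a, b) == 0

    def test_partner_toggle_flips_count(self):
        a, cage_with = _buried_polar_scene(True)
        assert buried_unsat_polars(a, cage_with) == 0
        a, cage_without = _buried_polar_scene(False)
        assert buried_unsat_polars(a, cage_without) == 1


class TestSurrogateScore:
    def test_separated_chains_score_zero(self):
        a = _single_atom()
        b = Structure()
        b.new_residue("B", 1, "UNK", [("C1", "C", (60.0, 0, 0))])
        assert surrogate_interface_score(a, b) == 0.0

    def test_adding_a_hydrogen_bond_strictly_decreases_score(self):
        base_a = Structure()
        base_a.new_residue(
            "A", 1, "XXX",
            [("N", "N", (0, 0, 0)), ("CC", "C", (-1.2, 0.7, 0))],
        )
        b_far = Structure()
        b_far.new_residue("B", 1, "XXX", [("O", "O", (4.5, 0, 0))])
        b_near = Structure()
        b_near.new_residue("B", 1, "XXX", [("O", "O", (2.9, 0, 0))])
        assert surrogate_interface_score(base_a, b_near) < surrogate_interface_score(
            base_a, b_far
        )

    def test_invariant_under_rigid_motion_of_whole_complex(self, contact_slabs):
        a, b = contact_slabs
        w = ScoreWeights(sphere_points=240)
        motion = RigidTransform.about_axis((1, 2, -1), 41.0, (3, -4, 5))
        s0 = surrogate_interface_score(a, b, w)
        s1 = surrogate_interface_score(a.transform(motion), b.transform(motion), w)
        assert s1 == pytest.approx(s0, abs=0.5)


def _glu_interface():
    """Toy interface where one glutamate makes the only hydrogen bonds."""
    ab = Structure()
    ab.new_residue(
        "H", 1, "GLU",
        [("N", "N", (0, 0, 6.0)), ("CA", "C", (1.4, 0.3, 6.2)),
         ("C", "C", (2.6, -0.3, 6.0)), ("O", "O", (2.7, -1.5, 6.2)),
         ("CB", "C", (1.5, 0.8, 4.8)), ("CG", "C", (1.6, 0.2, 3.5)),
         ("CD", "C", (1.7, 1.0, 2.3)),
         ("OE1", "O", (0.9, 2.0, 2.2)), ("OE2", "O", (2.5, 0.7, 1.4))],
    )
    for num, x in ((2, 6.0), (3, 10.0)):
        ab.new_residue(
            "H", num, "LEU",
            [("N", "N", (x, 0, 6.0)), ("CA", "C", (x + 1.4, 0.3, 6.2)),
             ("C", "C", (x + 2.6, -0.3, 6.0)), ("O", "O", (x + 2.7, -1.5, 6.2)),
             ("CB", "C", (x + 1.5, 0.8, 4.8))],
        )
    ag = Structure()
    # hydroxyl donors reaching the glutamate carboxylate oxygens, with
    # antecedents straight below so the donor angle is near 180 degrees
    ag.new_residue("A", 1, "XXX", [("OG", "O", (0.9, 2.0, -0.7)),
                                   ("CC", "C", (0.9, 2.0, -2.1))])
    ag.new_residue("A", 2, "XXX", [("OG", "O", (2.5, 0.7, -1.5)),
                                   ("CC", "C", (2.5, 0.7, -2.9))])
    n = 10
    for x in np.arange(-2, 14, 2.0):
        ag.new_residue("A", n, "UNK", [("C1", "C", (x, -2.0, 1.5))])
        n += 1
    return ab, ag


class TestAlanineScan:
    def test_dominant_glutamate_is_flagged_hotspot(self):
        ab, ag = _glu_interface()
        entries = alanine_scan(ab, ag, ScoreWeights(sphere_points=240))
        by_pos = {e.position.number: e for e in entries}
        assert 1 in by_pos
        glu = by_pos[1]
        assert glu.dscore == max(e.dscore for e in entries)
        assert glu.dscore > 0
        assert glu.hotspot

    def test_glycine_and_alanine_are_skipped(self):
        ab, ag = _glu_interface()
        gly = ab.copy()
        gly.get_residue(ResidueID("H", 2)).name = "GLY"
        entries = alanine_scan(gly, ag, ScoreWeights(sphere_points=240))
        assert all(e.position.number != 2 for e in entries)


class TestPointMutations:
    def test_combinatorics_and_forbidden_types(self):
        ab, ag = _glu_interface()
        positions = [ResidueID("H", n) for n in (1, 2, 3)]
        w = ScoreWeights(sphere_points=64)
        proposals = enumerate_point_mutations(ab, ag, positions, w)
        assert len(proposals) == 3 * 16
        assert all(p.to_type not in ("GLY", "PRO", "CYS") for p in proposals)
        assert all(p.to_type != p.from_type for p in proposals)

    def test_ranking_agrees_with_independent_rescoring(self):
        ab, ag = _glu_interface()
        w = ScoreWeights(sphere_points=64)
        positions = [ResidueID("H", 1)]
        proposals = enumerate_point_mutations(ab, ag, positions, w)
        wt = surrogate_interface_score(ab, ag, w)
        for p in proposals[:4] + proposals[-2:]:
            mutant = mutate_residue(ab, p.position, p.to_type)
            assert surrogate_interface_score(mutant, ag, w) - wt == pytest.approx(
                p.dscore, abs=1e-9
            )
        assert [p.rank for p in proposals] == sorted(p.rank for p in proposals)

    def test_proposal_to_forbidden_type_rejected_at_construction(self):
        with pytest.raises(ValueError):
            MutationProposal(ResidueID("H", 1), "ALA", "PRO", 0.0, 1)


def _design(sc, score):
    return ScoredDesign(
        f"d{sc}", None,
        InterfaceReport(100.0, sc, [], 0, score, [], []),
    )


class TestTriage:
    def test_graft_stage_rejects_sc_below_half(self):
        assert triage([_design(0.45, -5.0)], "graft") == []

    def test_swap_stage_rejects_what_graft_stage_retains(self):
        candidate = [_design(0.55, -5.0)]
        assert triage(candidate, "swap") == []
        assert len(triage(candidate, "graft")) == 1

    def test_top_k_keeps_five_lowest_scores(self):
        designs = [_design(0.8, s) for s in (3, -1, 7, -4, 0, 2, -9, 5, 1, -2)]
        kept = triage(designs, "graft", top_k=5)
        assert [d.report.surrogate_score for d in kept] == [-9, -4, -2, -1, 0]

    def test_raising_threshold_never_grows_accepted_set(self):
        designs = [_design(sc, 0.0) for sc in (0.3, 0.45, 0.55, 0.65, 0.8)]
        graft_kept = {d.design_id for d in triage(designs, "graft", top_k=10)}
        swap_kept = {d.design_id for d in triage(designs, "swap", top_k=10)}
        assert swap_kept <= graft_kept

    def test_nan_sc_is_rejected(self):
        assert triage([_design(float("nan"), -5.0)], "graft") == []
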