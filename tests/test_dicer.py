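"""Geometric distances, loop-counting rule, rule classification."""

import numpy as np
import pytest
from scipy.stats import ortho_group, spearmanr

from icshapemap import coords, dicer, simulate
from icshapemap.coords import CoordinateModel
from icshapemap.dicer import (
    DicingDistances,
    MirnaAnnotation,
    classify_rules,
    compare_isoforms,
    dicing_distances,
    loop_counting_check,
    terminus_distance,
)
from icshapemap.secondary import SecondaryStructure


def _point_model(points, energy=None):
    """points: dict residue -> xyz; C5' and O3' coincident."""
    model = CoordinateModel(energy=energy)
    for resid, xyz in points.items():
        model.set_atom(resid, "C5'", xyz)
        model.set_atom(resid, "O3'", xyz)
    return model


class TestTerminusDistance:
    def test_coincident_atoms_zero(self):
        model = _point_model({1: (0, 0, 0)})
        assert terminus_distance(model, 1, 1) == 0.0

    def test_three_four_five(self):
        model = _point_model({1: (0, 0, 0), 2: (3, 4, 0)})
        assert terminus_distance(model, 1, 2) == pytest.approx(5.0)

    def test_missing_atom_names_residue(self):
        model = CoordinateModel(name="m")
        model.set_atom(1, "C5'", (0, 0, 0))
        with pytest.raises(ValueError, match="residue 2.*O3"):
            terminus_distance(model, 1, 2)

    def test_legacy_star_atom_names(self):
        model = CoordinateModel()
        model.set_atom(1, "C5*", (0, 0, 0))
        model.set_atom(2, "O3*", (0, 0, 7))
        assert terminus_distance(model, 1, 2) == pytest.approx(7.0)

    def test_ideal_helix_matches_chord_formula(self):
        spec = simulate.HelixSpec(n_bp=25)
        model = simulate.build_helix_coordinates(spec)
        for n in (1, 4, 10, 20, 24):
            assert terminus_distance(model, 1, 1 + n) \
                == pytest.approx(spec.chord_distance(n), abs=1e-6)

    def test_rigid_motion_invariance(self):
        spec = simulate.HelixSpec(n_bp=15)
        model = simulate.build_helix_coordinates(spec)
        rot = ortho_group.rvs(3, random_state=3)
        moved = model.transformed(rot, (12.0, -8.0, 3.0))
        for a, b in [(1, 10), (4, 25), (2, 30)]:
            assert terminus_distance(moved, a, b) \
                == pytest.approx(terminus_distance(model, a, b), abs=1e-9)


HAIRPIN44 = "G" * 20 + "AAAA" + "C" * 20
STRUCT44 = SecondaryStructure.from_dotbracket(HAIRPIN44,
                                              "(" * 20 + "...." + ")" * 20)


class TestDicingDistances:
    def _annotation(self):
        return MirnaAnnotation("mir", HAIRPIN44, (1, 20), (23, 44))

    def test_single_model_equals_its_values(self):
        spec = simulate.HelixSpec(n_bp=22)
        model = simulate.build_helix_coordinates(spec)
        ann = self._annotation()
        dd = dicing_distances([model], ann, STRUCT44)
        assert dd.d_5p_mirna == pytest.approx(
            terminus_distance(model, 1, 20))
        assert dd.d_3p_mirna == pytest.approx(
            terminus_distance(model, 23, 44))
        assert dd.d_5p_arm == pytest.approx(terminus_distance(model, 1, 20))
        assert dd.d_3p_arm == pytest.approx(terminus_distance(model, 25, 44))

    def test_odd_count_median(self):
        anns = MirnaAnnotation("m", "GAAAGAAAC", (1, 4), (6, 9))
        models = [_point_model({1: (0, 0, 0), 4: (0, 0, 1), 6: (0, 0, 0),
                                9: (0, 0, d)}) for d in (58, 60, 59)]
        dd = dicing_distances(models, anns)
        assert dd.d_3p_mirna == 59.0

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            dicing_distances([], self._annotation())

    def test_median_robust_to_jitter(self):
        spec = simulate.HelixSpec(n_bp=22)
        noiseless = dicing_distances(
            [simulate.build_helix_coordinates(spec)], self._annotation())
        models = simulate.make_model_ensemble(spec, 50, sigma=0.5, seed=1)
        jittered = dicing_distances(models, self._annotation())
        assert abs(jittered.d_3p_mirna - noiseless.d_3p_mirna) < 1.0
        assert abs(jittered.d_5p_mirna - noiseless.d_5p_mirna) < 1.0

    def test_median_invariant_to_order_and_duplication(self):
        spec = simulate.HelixSpec(n_bp=22)
        models = simulate.make_model_ensemble(spec, 9, sigma=0.3, seed=2)
        ann = self._annotation()
        a = dicing_distances(models, ann)
        b = dicing_distances(models[::-1], ann)
        c = dicing_distances(models + models, ann)
        assert a.d_3p_mirna == b.d_3p_mirna == c.d_3p_mirna

    def test_lowest_energy_subset_used(self):
        ann = MirnaAnnotation("m", "GAAAGAAAC", (1, 4), (6, 9))
        points = {1: (0, 0, 0), 4: (0, 0, 1), 6: (0, 0, 0)}
        models = [_point_model({**points, 9: (0, 0, 59)}, energy=float(i))
                  for i in range(50)]
        models.append(_point_model({**points, 9: (0, 0, 100)},
                                   energy=1000.0))
        dd = dicing_distances(models, ann)
        assert dd.d_3p_mirna == 59.0  # the high-energy outlier is dropped


def hairpin_structure(stem: int, loop: int) -> SecondaryStructure:
    seq = "G" * stem + "A" * loop + "C" * stem
    return SecondaryStructure.from_dotbracket(
        seq, "(" * stem + "." * loop + ")" * stem)


def brute_force_rule_3p(structure: SecondaryStructure, p: int) -> bool:
    """Independent scan: exactly two paired nt between the nearest
    upstream single-stranded nucleotide and the 3p 5' end."""
    if p - 3 < 1:
        return False
    upstream = [q for q in range(1, p) if structure.is_unpaired(q)]
    if not upstream:
        return False
    nearest = max(upstream)
    between = [q for q in range(nearest + 1, p)
               if not structure.is_unpaired(q)]
    return nearest == p - 3 and len(between) == 2


# hand-built loop-counting cases: (structure, span_5p, span_3p, 3p, 5p)
_ST_7_4 = hairpin_structure(7, 4)          # loop 8..11, length 18
_ST_9_6 = hairpin_structure(9, 6)          # loop 10..15, length 24
_BULGED = SecondaryStructure.from_dotbracket(
    "GGGGAGGGAAAACCCCCCCC", "((((.(((....))).))))")  # ss at 5, 9-12, 16

LOOP_RULE_CASES = [
    # 3p start 14: 13, 12 paired, 11 in loop -> rule true
    (_ST_7_4, (1, 7), (14, 18), True, True),    # 5p end 7, pos 8 in loop
    (_ST_7_4, (1, 6), (14, 18), True, False),   # 5p end 6, pos 7 paired
    (_ST_7_4, (1, 7), (13, 18), False, True),   # only one paired nt between
    (_ST_7_4, (1, 7), (15, 18), False, True),   # three paired between
    (_ST_7_4, (1, 7), (12, 18), False, True),   # p-1 unpaired (in loop)
    (_ST_9_6, (1, 9), (18, 24), True, True),
    (_ST_9_6, (2, 9), (19, 24), False, True),
    (_ST_9_6, (1, 8), (18, 24), True, False),
    (_ST_9_6, (1, 9), (17, 24), False, True),
    (_ST_9_6, (1, 9), (20, 24), False, True),
    # bulge at 16 anchors the rule two paired nt downstream (p = 19)
    (_BULGED, (1, 4), (19, 20), True, True),    # 5p end 4, pos 5 = bulge
    (_BULGED, (1, 4), (18, 20), False, True),   # p-3 = 15 is paired
]


class TestLoopCountingRule:
    @pytest.mark.parametrize("structure, span5, span3, expect3, expect5",
                             LOOP_RULE_CASES)
    def test_hand_cases(self, structure, span5, span3, expect3, expect5):
        ann = MirnaAnnotation("m", structure.sequence, span5, span3)
        result = loop_counting_check(structure, ann)
        assert result["rule_3p"] is expect3
        assert result["rule_5p"] is expect5

    def test_span_touching_end_is_false(self):
        st = hairpin_structure(5, 4)  # length 14
        ann = MirnaAnnotation("m", st.sequence, (1, 5), (7, 14))
        res = loop_counting_check(st, ann)
        assert res["rule_3p"] is False  # p-3 < 1 territory is fine here;
        ann2 = MirnaAnnotation("m", st.sequence, (1, 10), (12, 14))
        # 5p end at 10 -> position 11 paired -> false
        res2 = loop_counting_check(st, ann2)
        assert res2["rule_5p"] is False

    def test_agrees_with_brute_force_scan(self):
        """20 structure/annotation combinations match the independent
        single-stranded-region scan exactly."""
        checked = 0
        for stem, loop in [(7, 4), (9, 6), (6, 5), (8, 3)]:
            st = hairpin_structure(stem, loop)
            n = len(st.sequence)
            for p in range(stem + loop - 1, min(stem + loop + 4, n)):
                ann = MirnaAnnotation("m", st.sequence,
                                      (1, min(stem, p - 2)), (p, n))
                got = loop_counting_check(st, ann)["rule_3p"]
                assert got == brute_force_rule_3p(st, p), (stem, loop, p)
                checked += 1
        assert checked >= 20


class TestClassifyRules:
    def test_membership_examples(self):
        loop = {"rule_3p": True, "rule_5p": False}
        d = DicingDistances(59.0, 59.5)
        assert classify_rules(d, loop) == {
            "loop_counting": True, "three_prime": True, "five_prime": True}
        d2 = DicingDistances(59.0, 57.9)
        assert classify_rules(d2, loop)["three_prime"] is False

    def test_boundary_inclusive(self):
        d = DicingDistances(58.0, 60.0)
        out = classify_rules(d, {"rule_3p": False, "rule_5p": False})
        assert out["three_prime"] is True and out["five_prime"] is True

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(5)
        loop = {"rule_3p": False, "rule_5p": False}
        for _ in range(50):
            d = DicingDistances(rng.uniform(50, 70), rng.uniform(50, 70))
            members = [classify_rules(d, loop, tol=t) for t in
                       (0.0, 0.5, 1.0, 2.0)]
            for a, b in zip(members, members[1:]):
                for key in ("three_prime", "five_prime"):
                    assert not (a[key] and not b[key])


class TestCompareIsoforms:
    def _models_at(self, d3, p, length):
        return [_point_model({1: (0, 0, 0), p: (0, 0, 0),
                              length: (0, 0, d3)})]

    def test_in_range_share(self):
        seq = "G" * 10 + "AAAA" + "C" * 10
        ann = MirnaAnnotation("m", seq, (1, 10), (15, 24))
        models = {0: self._models_at(59.0, 15, 24),
                  1: self._models_at(55.0, 16, 24)}
        table, summary = compare_isoforms(models, ann, {0: 80, 1: 20})
        assert summary["in_range_share"] == pytest.approx(0.8)
        assert summary["annotated_is_closest"] is True

    def test_zero_counts_rejected(self):
        seq = "G" * 10 + "AAAA" + "C" * 10
        ann = MirnaAnnotation("m", seq, (1, 10), (15, 24))
        models = {0: self._models_at(59.0, 15, 24),
                  1: self._models_at(55.0, 16, 24)}
        with pytest.raises(ValueError, match="zero total"):
            compare_isoforms(models, ann, {0: 0, 1: 0})

    def test_monotone_share_distance_relation(self):
        """Shares planted to fall with |D - 59| give a positive Spearman
        correlation between share and -|D - 59| over 10 isoforms."""
        spec = simulate.HelixSpec(n_bp=40)
        base = simulate.build_helix_coordinates(spec)
        rng = np.random.default_rng(8)
        seq = "G" * 38 + "AAAA" + "C" * 38
        ann = MirnaAnnotation("m", seq, (1, 30), (55, 80))
        offsets = list(range(-4, 6))
        models, counts, devs = {}, {}, {}
        for off in offsets:
            models[off] = [base.jittered(0.3, rng) for _ in range(5)]
            p = 55 + off
            d = spec.chord_distance(80 - p)
            devs[off] = abs(d - 59.0)
            counts[off] = max(1.0, 1000.0 - 150.0 * devs[off])
        table, _ = compare_isoforms(models, ann, counts)
        rho = spearmanr(table["share"], -table["abs_deviation"])[0]
        assert rho > 0


class TestPdbRoundTrip:
    def test_models_survive_pdb_io(self, tmp_path):
        spec = simulate.HelixSpec(n_bp=6)
        models = simulate.make_model_ensemble(spec, 3, sigma=0.2, seed=4)
        path = tmp_path / "models.pdb"
        coords.write_pdb_models(path, models)
        back = coords.read_pdb_models(path)
        assert len(back) == 3
        for orig, rec in zip(models, back):
            assert rec.energy == pytest.approx(orig.energy)
            for key, xyz in orig.atoms.items():
                assert np.allclose(rec.atoms[key], xyz, atol=1e-3)
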