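"""Gamete and zygote distributions under linkage and gamete lethality."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import grainlink as gl
from conftest import oracle_gamete_frequencies, random_lethality, random_map_and_parent

SETTINGS = dict(
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)


class TestGameteFrequencies:
    def test_double_heterozygote_loses_quarter_of_gametes(self, d60_f1, two_locus_map):
        """D60d60 Galgal sheds three surviving gamete classes at 1/3 each,
        fertility 75%."""
        rule = gl.LethalityRule((frozenset({"d60", "gal"}),))
        gd = gl.gamete_frequencies(d60_f1, rule=rule)
        assert gd.fertility == pytest.approx(0.75)
        expected = {
            ("D60", "Gal"): 1 / 3,
            ("D60", "gal"): 1 / 3,
            ("d60", "Gal"): 1 / 3,
        }
        assert set(gd.frequencies) == set(expected)
        for h, p in expected.items():
            assert gd.frequencies[h] == pytest.approx(p)

    def test_mendelian_identity_without_rule(self, d60_f1):
        gd = gl.gamete_frequencies(d60_f1)
        assert gd.fertility == 1.0
        assert len(gd.frequencies) == 4
        assert all(p == pytest.approx(0.25) for p in gd.frequencies.values())

    def test_three_locus_complete_linkage_survivors(self, lmap, rule):
        """With r(GW2,d60)=0 the coupling F1 keeps three haplotypes at 1/3."""
        m0 = gl.default_map(r=0.0)
        f1 = gl.PhasedGenotype.from_haplotypes(
            m0, ("GW2", "d60", "Gal"), ("gw2", "D60", "gal")
        )
        gd = gl.gamete_frequencies(f1, rule=rule)
        expected = {
            ("GW2", "d60", "Gal"): 1 / 3,
            ("gw2", "D60", "Gal"): 1 / 3,
            ("gw2", "D60", "gal"): 1 / 3,
        }
        assert gd.fertility == pytest.approx(0.75)
        assert {h: pytest.approx(p) for h, p in expected.items()} == gd.frequencies

    def test_illegal_allele_rejected(self, lmap):
        with pytest.raises(gl.InvalidGenotypeError):
            gl.PhasedGenotype.from_haplotypes(
                lmap, ("GW2", "d60", "WRONG"), ("gw2", "D60", "gal")
            )

    def test_sex_restricted_rule_spares_other_sex(self, d60_f1):
        rule = gl.LethalityRule((frozenset({"d60", "gal"}),), sexes="male")
        male = gl.gamete_frequencies(d60_f1, rule=rule, sex="male")
        female = gl.gamete_frequencies(d60_f1, rule=rule, sex="female")
        assert male.fertility == pytest.approx(0.75)
        assert female.fertility == 1.0
        assert len(female.frequencies) == 4

    @given(mp=random_map_and_parent())
    @settings(max_examples=60, **SETTINGS)
    def test_frequencies_sum_to_one(self, mp):
        lmap, parent = mp
        gd = gl.gamete_frequencies(parent)
        assert math.isclose(sum(gd.frequencies.values()), 1.0, abs_tol=1e-12)

    @given(mp=random_map_and_parent(), data=st.data())
    @settings(max_examples=60, **SETTINGS)
    def test_matches_enumeration_oracle(self, mp, data):
        """Implementation equals exhaustive start-strand x crossover enumeration."""
        lmap, parent = mp
        rule = data.draw(random_lethality(lmap))
        try:
            gd = gl.gamete_frequencies(parent, rule=rule, sex="female")
        except gl.GrainlinkError:
            # all gametes lethal (parent homozygous for the lethal combo)
            oracle, fert = oracle_gamete_frequencies(
                parent, lmap, rule=None, sex=None
            )
            assert all(rule.is_lethal(h) for h in oracle)
            return
        oracle, fert = oracle_gamete_frequencies(parent, lmap, rule, "female")
        assert gd.fertility == pytest.approx(fert, abs=1e-12)
        assert set(gd.frequencies) == set(oracle)
        for h, p in oracle.items():
            assert gd.frequencies[h] == pytest.approx(p, abs=1e-12)


class TestZygoteDistribution:
    def test_selfing_f1_gives_6_2_1_culm_classes(self, d60_f1, two_locus_map):
        rule = gl.LethalityRule((frozenset({"d60", "gal"}),))
        gd = gl.gamete_frequencies(d60_f1, rule=rule)
        z = gl.zygote_distribution(gd, gd)
        assert sum(z.values()) == pytest.approx(1.0, abs=1e-12)
        culm = gl.culm_classifier(
            two_locus_map.locus("D60"), two_locus_map.locus("Gal")
        )
        probs = gl.expected_class_probabilities(z, culm, two_locus_map)
        assert probs["long-stem"] == pytest.approx(6 / 9)
        assert probs["partially sterile"] == pytest.approx(2 / 9)
        assert probs["semidwarf"] == pytest.approx(1 / 9)

    def test_fixed_parents_give_single_genotype(self, lmap):
        a = gl.PhasedGenotype.homozygous(lmap, ("GW2", "d60", "Gal"))
        b = gl.PhasedGenotype.homozygous(lmap, ("gw2", "D60", "gal"))
        z = gl.zygote_distribution(
            gl.gamete_frequencies(a), gl.gamete_frequencies(b)
        )
        assert len(z) == 1
        assert next(iter(z.values())) == pytest.approx(1.0)

    def test_complete_linkage_carrier_ratio_5_to_4(self, rule):
        """At r=0 the selfed coupling F1 gives P(GW2 carrier)=5/9, P(gw2gw2)=4/9."""
        m0 = gl.default_map(r=0.0)
        f1 = gl.PhasedGenotype.from_haplotypes(
            m0, ("GW2", "d60", "Gal"), ("gw2", "D60", "gal")
        )
        gd = gl.gamete_frequencies(f1, rule=rule)
        z = gl.zygote_distribution(gd, gd)
        g2 = gl.grain_classifier(m0.locus("GW2"), mode="complete")
        probs = gl.expected_class_probabilities(z, g2, m0)
        assert probs["large"] == pytest.approx(5 / 9)
        assert probs["small"] == pytest.approx(4 / 9)

    def test_mismatched_locus_sets_rejected(self, d60_f1, f1):
        a = gl.gamete_frequencies(d60_f1)
        b = gl.gamete_frequencies(f1)
        with pytest.raises(gl.IncompatibleGametesError):
            gl.zygote_distribution(a, b)

    @given(mp=random_map_and_parent(max_loci=3))
    @settings(max_examples=40, **SETTINGS)
    def test_zygote_distribution_sums_to_one(self, mp):
        _, parent = mp
        gd = gl.gamete_frequencies(parent)
        z = gl.zygote_distribution(gd, gd)
        assert math.isclose(sum(z.values()), 1.0, abs_tol=1e-12)


class TestExpectedClassProbabilities:
    def test_two_locus_f2_reproduces_9_3_3_1(self):
        """Empty rule, r=0.5: the dominant-class dihybrid ratio is exact."""
        a = gl.Locus("A", ("A", "a"))
        b = gl.Locus("B", ("B", "b"))
        lmap = gl.LinkageMap((gl.LinkageGroup((a, b), (0.5,)),))
        f1 = gl.PhasedGenotype.from_haplotypes(lmap, ("A", "B"), ("a", "b"))
        gd = gl.gamete_frequencies(f1)
        z = gl.zygote_distribution(gd, gd)

        def dom(pairs):
            return ("A" if "A" in pairs["A"] else "a") + (
                "B" if "B" in pairs["B"] else "b"
            )

        cls = gl.PhenotypeClassifier("dihybrid", ("AB", "Ab", "aB", "ab"), ("A", "B"), dom)
        probs = gl.expected_class_probabilities(z, cls, lmap)
        assert probs["AB"] == pytest.approx(9 / 16)
        assert probs["Ab"] == pytest.approx(3 / 16)
        assert probs["aB"] == pytest.approx(3 / 16)
        assert probs["ab"] == pytest.approx(1 / 16)

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.176, 0.3, 0.5])
    def test_culm_classes_invariant_to_grain_linkage(self, r, rule):
        """The 1:2:6 culm ratio does not depend on r(GW2, d60)."""
        design = gl.builtin_design("bc1f2", r=r)
        culm = gl.culm_classifier(design.lmap.locus("D60"), design.lmap.locus("Gal"))
        probs = gl.expected_class_probabilities(design, culm)
        assert probs["semidwarf"] == pytest.approx(1 / 9)
        assert probs["partially sterile"] == pytest.approx(2 / 9)
        assert probs["long-stem"] == pytest.approx(6 / 9)

    def test_independence_gives_6_and_2_of_36(self):
        design = gl.builtin_design("bc4f2", r=0.5)
        joint = gl.joint_classifier(
            gl.grain_classifier(design.lmap.locus("GW2")),
            gl.culm_classifier(design.lmap.locus("D60"), design.lmap.locus("Gal")),
        )
        probs = gl.expected_class_probabilities(design, joint)
        assert probs["large & long-stem"] == pytest.approx(6 / 36)
        assert probs["large & partially sterile"] == pytest.approx(2 / 36)

    def test_degenerate_distribution_for_fixed_line(self, lmap, grain):
        a = gl.PhasedGenotype.homozygous(lmap, ("GW2", "d60", "Gal"))
        z = gl.zygote_distribution(
            gl.gamete_frequencies(a), gl.gamete_frequencies(a)
        )
        probs = gl.expected_class_probabilities(z, grain, lmap)
        assert probs == {"large": 1.0, "medium": 0.0, "small": 0.0}

    def test_recessive_class_small_grain_fraction_increases_with_r(self):
        """P(gw2gw2 | semidwarf) is r^2: zero at r=0, strictly increasing."""
        values = []
        for r in np.linspace(0.0, 0.5, 11):
            design = gl.builtin_design("bc4f2", r=float(r))
            joint = gl.joint_classifier(
                gl.grain_classifier(design.lmap.locus("GW2")),
                gl.culm_classifier(design.lmap.locus("D60"), design.lmap.locus("Gal")),
            )
            probs = gl.expected_class_probabilities(design, joint)
            semidwarf = sum(v for k, v in probs.items() if k.endswith("semidwarf"))
            values.append(probs["small & semidwarf"] / semidwarf)
        assert values[0] == pytest.approx(0.0, abs=1e-12)
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.25)  # r=0.5 -> r^2 = 1/4


class TestClassify:
    @pytest.mark.parametrize(
        "haps,expected",
        [
            ((("gw2", "d60", "Gal"), ("gw2", "d60", "Gal")), "semidwarf"),
            ((("gw2", "d60", "Gal"), ("gw2", "D60", "gal")), "partially sterile"),
            ((("gw2", "D60", "gal"), ("gw2", "D60", "gal")), "long-stem"),
            ((("gw2", "d60", "Gal"), ("gw2", "D60", "Gal")), "long-stem"),
        ],
    )
    def test_culm_rule(self, lmap, culm, haps, expected):
        g = gl.PhasedGenotype(lmap, haps)
        assert gl.classify(g, culm) == expected

    @pytest.mark.parametrize(
        "pair,expected",
        [(("GW2", "GW2"), "large"), (("GW2", "gw2"), "medium"), (("gw2", "gw2"), "small")],
    )
    def test_grain_rule_incomplete_dominance(self, lmap, grain, pair, expected):
        g = gl.PhasedGenotype.from_haplotypes(
            lmap, (pair[0], "D60", "gal"), (pair[1], "D60", "gal")
        )
        assert gl.classify(g, grain) == expected

    def test_classifier_missing_locus_errors(self, culm, lmap):
        with pytest.raises(gl.ClassificationError):
            culm({"GW2": ("GW2", "gw2")})

    def test_fertility_is_a_genotype_property(self, f1, lmap, rule):
        assert gl.fertility_of(f1, rule) == pytest.approx(0.75)
        semidwarf = gl.PhasedGenotype.homozygous(lmap, ("gw2", "d60", "Gal"))
        assert gl.fertility_of(semidwarf, rule) == 1.0
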