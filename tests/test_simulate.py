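"""Breeding-scheme simulator: sampling, selection, markers, phenotypes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import grainlink as gl


class TestSimulatePopulation:
    def test_d60_f2_culm_classes_fit_6_2_1(self):
        """10,000 F2 of Koshihikari d60 x Inochinoichi: culm classes fit the
        lethality-model 1:2:6 (semidwarf : partially sterile : long-stem)."""
        design = gl.builtin_design("d60-f2")
        pop = gl.simulate_population(design, n=10_000, seed=3)
        culm = gl.culm_classifier(design.lmap.locus("D60"), design.lmap.locus("Gal"))
        table = pop.counts(culm, ratio=(1, 2, 6))
        assert gl.chi_square_gof(table).pvalue > 0.01

    def test_single_offspring_of_fixed_parents_is_the_f1(self):
        design = gl.builtin_design("bc1f2")
        pops = gl.simulate_population(design, seed=11, return_all=True)
        f1 = pops["BC1F2-F1"]
        assert f1.size == 1
        g = f1.genotype(0)
        assert sorted(g.haplotypes) == sorted(
            [("GW2", "d60", "Gal"), ("gw2", "D60", "gal")]
        )

    def test_no_lethality_single_locus_f2_is_1_2_1(self):
        """With the rule removed, the d60 genotype ratio reverts to Mendelian."""
        design = gl.builtin_design("d60-f2")
        design.rule = None
        pop = gl.simulate_population(design, n=8000, seed=5)
        codes = pop.codes_frame()["D60"]
        table = gl.ClassCountTable(
            ("A/A", "A/B", "B/B"),
            tuple(int((codes == c).sum()) for c in ("A/A", "A/B", "B/B")),
            ratio=(1, 2, 1),
        )
        assert gl.chi_square_gof(table).pvalue > 0.001

    def test_f1_fertility_is_exactly_75_percent(self):
        pops = gl.simulate_population(
            gl.builtin_design("bc1f2"), seed=2, return_all=True
        )
        assert pops["BC1F2-F1"].fertility() == pytest.approx([0.75])

    def test_semidwarf_class_often_lacks_small_grain_at_n_157(self):
        """At r = 0.176 the conditional P(gw2gw2 | semidwarf) is r^2 ~ 0.031,
        so with ~17 semidwarfs per population many seeds show zero — the
        configuration the field data reported (11:6:0)."""
        design = gl.builtin_design("bc4f2", r=0.176)
        grain = gl.grain_classifier(design.lmap.locus("GW2"))
        zero_fraction = 0
        n_seeds = 60
        for seed in range(n_seeds):
            pop = gl.simulate_population(design, n=157, seed=seed)
            semidwarf = pop.filter({"D60": "A/A"})
            if semidwarf.size == 0:
                continue
            counts = semidwarf.counts(grain).observed
            if counts[2] == 0:
                zero_fraction += 1
        zero_fraction /= n_seeds
        assert 0.3 < zero_fraction < 0.9

    def test_seeded_rerun_writes_identical_csv(self, tmp_path):
        design = gl.builtin_design("bc4f2")
        paths = []
        for name in ("a.csv", "b.csv"):
            pop = gl.simulate_population(
                design, n=60, seed=9, phenomodel=gl.PhenotypeModel()
            )
            p = tmp_path / name
            pop.to_csv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "a.csv.provenance.json").exists()

    def test_unsatisfiable_selection_names_the_step(self):
        design = gl.builtin_design("f2")
        design.steps = design.steps + (
            gl.SelectStep("impossible", "F2", {"GW2": ("nonsense",)}),
        )
        with pytest.raises(gl.SelectionError, match="impossible"):
            gl.simulate_population(design, seed=1)

    def test_select_first_is_reproducible_and_single(self):
        design = gl.builtin_design("f2")
        design.steps = design.steps + (
            gl.SelectStep("pick", "F2", {"GW2": "A/A"}),
        )
        a = gl.simulate_population(design, seed=4)
        b = gl.simulate_population(design, seed=4)
        assert a.size == b.size == 1
        assert a.genotype(0).haplotypes == b.genotype(0).haplotypes


class TestMarkers:
    def test_marker_at_trait_locus_matches_trait_genotype(self):
        pop = gl.simulate_population(
            gl.builtin_design("nipponbare-f2"), n=500, seed=13
        )
        popm = gl.attach_markers(pop, {"M_at": 8.1})
        df = popm.codes_frame()
        assert (df["M_at"] == df["GW2"]).all()

    def test_marker_20_cm_away_shows_haldane_recombination(self):
        """Observed marker-trait recombination over the recessive class
        approaches 100 x haldane(20 cM)."""
        expected = 100 * gl.haldane_d_to_r(20.0)
        values = []
        for seed in (17, 18, 19, 20):
            pop = gl.simulate_population(
                gl.builtin_design("nipponbare-f2"), n=6000, seed=seed
            )
            popm = gl.attach_markers(pop, {"M20": 13.1})  # 5 Mb * 4 cM/Mb
            rec = popm.filter({"GW2": "B/B"})
            out = gl.marker_trait_recombination(rec.marker_table(), {"M20": 13.1})
            values.append(out.loc[0, "recombination_value"])
        assert np.mean(values) == pytest.approx(expected, abs=3.0)

    def test_flanking_markers_show_no_interference(self):
        """Gametes recombinant in both flanking intervals occur at the
        product of the single-interval frequencies (scored directly on the
        sampled gamete haplotypes)."""
        pop = gl.simulate_population(
            gl.builtin_design("nipponbare-f2"), n=30_000, seed=23
        )
        popm = gl.attach_markers(pop, {"L": 5.6, "R": 10.6})  # 10 cM each side
        lm = popm.lmap
        iL, iG, iR = lm.index("L"), lm.index("GW2"), lm.index("R")

        def double_flags(haps):
            return np.array(
                [
                    ((h[iL] == "L.A") != (h[iG] == "GW2"))
                    and ((h[iG] == "GW2") != (h[iR] == "R.A"))
                    for h in haps
                ]
            )

        flags = np.concatenate(
            [
                double_flags(popm.mother_haps)[popm.idx_mother],
                double_flags(popm.father_haps)[popm.idx_father],
            ]
        )
        r_single = gl.haldane_d_to_r(10.0)
        assert flags.mean() == pytest.approx(r_single**2, abs=0.002)

    def test_marker_off_chromosome_rejected(self):
        pop = gl.simulate_population(gl.builtin_design("nipponbare-f2"), n=10, seed=1)
        mm = pd.DataFrame(
            {"marker": ["MX"], "chromosome": ["7"], "position_mb": [8.0]}
        )
        with pytest.raises(gl.PlacementError):
            gl.attach_markers(pop, mm)


class TestPhenotypes:
    def test_zero_sd_traits_equal_class_means(self):
        model = gl.PhenotypeModel(grain_sd=1e-12, culm_sd=1e-12)
        pop = gl.simulate_population(
            gl.builtin_design("d60-f2"), n=300, seed=6, phenomodel=model
        )
        for label, mean in model.grain_means.items():
            sel = pop.traits["grain_class"] == label
            if sel.any():
                assert pop.traits.loc[sel, "grain_area"].to_numpy() == pytest.approx(
                    mean
                )

    def test_threshold_classifier_recovers_true_class(self):
        """Default means and sd separate the classes: >95% of individuals
        are assigned their genotypic grain class by the midpoint thresholds."""
        pop = gl.simulate_population(
            gl.builtin_design("f2"), n=10_000, seed=8, phenomodel=gl.PhenotypeModel()
        )
        rule = gl.default_grain_rule()
        recovered = np.array(
            [rule.classify_value(x) for x in pop.traits["grain_area"]]
        )
        accuracy = (recovered == pop.traits["grain_class"].to_numpy()).mean()
        assert accuracy > 0.95

    def test_partial_sterility_tracks_genotype_not_noise(self):
        pop = gl.simulate_population(
            gl.builtin_design("d60-f2"), n=2000, seed=10, phenomodel=gl.PhenotypeModel()
        )
        ps = pop.traits["culm_class"] == "partially sterile"
        assert (pop.traits.loc[ps, "fertility"] == 0.75).all()
        assert (pop.traits.loc[~ps, "fertility"] == 1.0).all()

    def test_misordered_means_rejected(self):
        with pytest.raises(gl.DesignError):
            gl.PhenotypeModel(grain_means={"small": 24.0, "medium": 22.0, "large": 25.0})


class TestAnalyticDistribution:
    def test_matches_simulation_frequencies(self):
        """Analytic phased-genotype distribution agrees with the empirical
        frequencies of a large simulated population."""
        design = gl.builtin_design("bc1f2")
        dist = gl.analytic_genotype_distribution(design)
        pop = gl.simulate_population(design, n=40_000, seed=21)
        culm = gl.culm_classifier(design.lmap.locus("D60"), design.lmap.locus("Gal"))
        probs = gl.expected_class_probabilities(dist, culm, design.lmap)
        counts = pop.counts(culm)
        for label, c in zip(counts.labels, counts.observed):
            assert c / pop.size == pytest.approx(probs[label], abs=0.01)

    def test_selection_conditions_the_distribution(self):
        design = gl.builtin_design("f2")
        design.steps = design.steps + (
            gl.SelectStep("rec", "F2", {"GW2": "B/B"}, keep="all"),
        )
        dist = gl.analytic_genotype_distribution(design)
        grain = gl.grain_classifier(design.lmap.locus("GW2"))
        probs = gl.expected_class_probabilities(dist, grain, design.lmap)
        assert probs["small"] == pytest.approx(1.0)

    def test_phenotype_predicates_have_no_analytic_counterpart(self):
        design = gl.builtin_design("f2")
        design.steps = design.steps + (
            gl.SelectStep("phen", "F2", lambda row: row["grain_area"] > 23),
        )
        with pytest.raises(gl.DesignError):
            gl.analytic_genotype_distribution(design)
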