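"""Virtual individual construction, scaling, ontogeny, impairment, sampling."""

import numpy as np
import pytest

from henapbpk.physiology import (ImpairmentScaling, PopulationSpec,
                                 apply_hepatic_impairment, apply_ontogeny,
                                 gfr_maturation,
                                 ontogeny_factor, population_to_frame,
                                 sample_population, scale_to_age,
                                 _growth_lookup)

UGTS = ("UGT1A9", "UGT2B7", "UGT1A3")


class TestReferenceAdult:
    def test_demographics(self, adult):
        assert adult.age == 30
        assert adult.sex == "male"

    def test_enzyme_multipliers_unity(self, adult):
        assert all(v == 1.0 for v in adult.enzyme_expression.values())

    def test_flows_sum_to_cardiac_output(self, adult):
        assert adult.systemic_flow_sum() == pytest.approx(adult.cardiac_output,
                                                          rel=0.01)


class TestAgeScaling:
    def test_identity_at_reference_age(self, adult):
        scaled = scale_to_age(adult, 30.0, "male")
        assert scaled.weight == pytest.approx(adult.weight)
        for organ in adult.organs:
            assert scaled.organs[organ]["volume"] == pytest.approx(
                adult.organs[organ]["volume"], rel=1e-9)
            assert scaled.organs[organ]["blood_flow"] == pytest.approx(
                adult.organs[organ]["blood_flow"], rel=1e-9)
        assert scaled.gfr == pytest.approx(adult.gfr, rel=1e-9)

    def test_neonate_weight_and_gfr(self, adult):
        neo = scale_to_age(adult, 0.02, "male")
        expected_w, _ = _growth_lookup(0.02, "male")
        assert neo.weight == pytest.approx(expected_w)
        assert neo.weight < 4.0
        assert gfr_maturation(0.02) < 0.5

    def test_weight_monotone_through_childhood(self, adult):
        ages = np.linspace(0, 18, 80)
        for sex in ("male", "female"):
            weights = [scale_to_age(adult, a, sex).weight for a in ages]
            assert np.all(np.diff(weights) >= -1e-12)

    def test_scaled_flows_still_sum_to_co(self, adult):
        child = scale_to_age(adult, 6.0, "female")
        assert child.systemic_flow_sum() == pytest.approx(child.cardiac_output,
                                                          rel=0.01)

    def test_age_out_of_range(self, adult):
        with pytest.raises(ValueError):
            scale_to_age(adult, 150.0, "male")


class TestOntogeny:
    def test_adult_factors_are_one(self, adult):
        out = apply_ontogeny(adult)
        assert all(out.enzyme_expression[e] == 1.0 for e in UGTS)

    @pytest.mark.parametrize("enzyme", UGTS)
    def test_monotone_increasing_with_age(self, enzyme):
        ages = np.linspace(0, 12, 50)
        factors = [ontogeny_factor(enzyme, a) for a in ages]
        assert np.all(np.diff(factors) > 0)

    def test_subgroup_midpoint_ordering_ugt1a9(self):
        neonate = ontogeny_factor("UGT1A9", 14 / 365.25)
        infant = ontogeny_factor("UGT1A9", 1.0)
        child = ontogeny_factor("UGT1A9", 6.5)
        assert neonate < infant < child

    def test_bounds(self, adult):
        for age in (0.0, 0.5, 3.0, 10.0, 17.9, 18.0, 40.0):
            ind = apply_ontogeny(scale_to_age(adult, age, "male"))
            for e, v in ind.enzyme_expression.items():
                assert 0 < v <= 1.2
                if age >= 18:
                    assert v == 1.0


class TestHepaticImpairment:
    def test_healthy_grade_is_identity(self, adult):
        healthy = apply_hepatic_impairment(adult, ImpairmentScaling.for_grade("healthy"))
        assert healthy.organs == adult.organs
        assert healthy.hematocrit == adult.hematocrit
        assert healthy.enzyme_expression == adult.enzyme_expression
        assert healthy.gfr == adult.gfr

    def test_cpc_scalers(self, adult):
        cpc = apply_hepatic_impairment(adult, ImpairmentScaling.for_grade("CP-C"))
        assert cpc.organs["small_intestine"]["blood_flow"] == pytest.approx(
            adult.organs["small_intestine"]["blood_flow"] * 0.04)
        assert cpc.organs["liver"]["volume"] == pytest.approx(
            adult.organs["liver"]["volume"] * 0.28)

    def test_cpb_enzymes_and_gfr(self, adult):
        cpb = apply_hepatic_impairment(adult, ImpairmentScaling.for_grade("CP-B"))
        assert cpb.enzyme_expression["UGT2B7"] == pytest.approx(0.30)
        assert cpb.gfr == pytest.approx(adult.gfr * 0.70)

    def test_brain_flow_unchanged(self, adult):
        cpc = apply_hepatic_impairment(adult, ImpairmentScaling.for_grade("CP-C"))
        assert cpc.organs["brain"]["blood_flow"] == pytest.approx(
            adult.organs["brain"]["blood_flow"])

    def test_pediatric_rejected(self, adult):
        child = scale_to_age(adult, 8.0, "male")
        with pytest.raises(ValueError):
            apply_hepatic_impairment(child, ImpairmentScaling.for_grade("CP-A"))

    def test_hepatic_capacity_strictly_decreasing(self, adult):
        """Sum(enzyme factor x fm weight) x liver volume fraction falls with grade."""
        weights = {"UGT1A9": 0.47, "UGT2B7": 0.30, "UGT1A3": 0.09, "CYP3A4": 0.11}
        capacities = []
        for grade in ("healthy", "CP-A", "CP-B", "CP-C"):
            s = ImpairmentScaling.for_grade(grade)
            cap = s.liver_volume_fraction * sum(
                weights[e] * s.enzyme_conc_factors[e] for e in weights)
            capacities.append(cap)
        assert np.all(np.diff(capacities) < 0)


class TestPopulationSampling:
    def test_exact_sex_split(self):
        pop = sample_population(PopulationSpec(n=100, subgroup="adult",
                                               sex_ratio=0.5, seed=1))
        assert sum(1 for p in pop if p.sex == "female") == 50

    def test_seeded_reproducibility(self):
        spec = PopulationSpec(n=20, subgroup="child", seed=7)
        a = population_to_frame(sample_population(spec))
        b = population_to_frame(sample_population(PopulationSpec(
            n=20, subgroup="child", seed=7)))
        assert a.equals(b)

    def test_adolescent_ages_in_bounds(self):
        pop = sample_population(PopulationSpec(n=50, subgroup="adolescent", seed=3))
        assert all(12.0 <= p.age <= 18.0 for p in pop)

    def test_empty_age_range_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(n=5, subgroup="adult", age_range=(40, 20))

    def test_mean_weight_tracks_growth_table(self, adult):
        """Lognormal variability is mean-preserving: population mean weight
        stays within 5% of the deterministic growth-table expectation."""
        spec = PopulationSpec(n=1000, subgroup="child", seed=11)
        pop = sample_population(spec)
        mean_weight = np.mean([p.weight for p in pop])
        ages = np.array([p.age for p in pop])
        sexes = [p.sex for p in pop]
        expected = np.mean([_growth_lookup(a, s)[0] for a, s in zip(ages, sexes)])
        assert mean_weight == pytest.approx(expected, rel=0.05)
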