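"""Sensitivity methods against closed-form indices, and PBPK application."""

import pytest

from henapbpk import DosingRegimen
from henapbpk.sensitivity import (ParameterEntry, ParameterSpace, efast,
                                  lsa_oat, make_exposure_runner,
                                  morris_screening)

UNIT2 = [ParameterEntry("x1", 0.5, (0.0, 1.0)), ParameterEntry("x2", 0.5, (0.0, 1.0))]


class TestMorris:
    def test_linear_function_exact(self):
        space = ParameterSpace(list(UNIT2), seed=1)
        result = morris_screening(lambda p: p["x1"], space, r_trajectories=6)
        mu1, sigma1 = result["x1"]
        mu2, _ = result["x2"]
        assert mu1 == pytest.approx(1.0)
        assert sigma1 == pytest.approx(0.0, abs=1e-12)
        assert mu2 == 0.0

    def test_interaction_disperses_elementary_effects(self):
        space = ParameterSpace(list(UNIT2), seed=2)
        result = morris_screening(lambda p: p["x1"] * p["x2"], space,
                                  r_trajectories=10)
        assert result["x1"][1] > 0.1  # sigma reveals the interaction

    def test_seeded_reproducibility(self):
        space = ParameterSpace(list(UNIT2), seed=5)
        f = lambda p: p["x1"] + 0.5 * p["x2"] ** 2
        assert morris_screening(f, space) == morris_screening(f, space)

    def test_too_few_trajectories_rejected(self):
        with pytest.raises(ValueError):
            morris_screening(lambda p: 0.0, ParameterSpace(list(UNIT2)),
                             r_trajectories=1)


class TestEfast:
    def test_additive_linear_variance_split(self):
        """f = 2 x1 + x2 on equal-width inputs: S1 = 4/5, S2 = 1/5."""
        space = ParameterSpace(list(UNIT2), seed=3)
        result = efast(lambda p: 2 * p["x1"] + p["x2"], space)
        assert result["x1"][0] == pytest.approx(0.8, abs=0.05)
        assert result["x2"][0] == pytest.approx(0.2, abs=0.05)

    def test_pure_interaction(self):
        space = ParameterSpace([ParameterEntry("x1", 0.0, (-1.0, 1.0)),
                                ParameterEntry("x2", 0.0, (-1.0, 1.0))], seed=4)
        result = efast(lambda p: p["x1"] * p["x2"], space)
        for name in ("x1", "x2"):
            s_i, s_ti = result[name]
            assert s_i == pytest.approx(0.0, abs=0.05)
            assert s_ti == pytest.approx(1.0, abs=0.05)

    def test_first_order_bounded_by_total(self):
        space = ParameterSpace(list(UNIT2), seed=6)
        result = efast(lambda p: p["x1"] ** 2 + p["x1"] * p["x2"], space)
        for s_i, s_ti in result.values():
            assert s_i <= s_ti + 0.02

    def test_aliasing_guard(self):
        space = ParameterSpace(list(UNIT2))
        with pytest.raises(ValueError, match="alias"):
            efast(lambda p: 0.0, space, n_samples=33, interference_factor=4)


@pytest.fixture(scope="module")
def runner(compound, adult):
    return make_exposure_runner(compound, adult, DosingRegimen(dose=5),
                                metric="auc")


class TestLocalSensitivityOnPBPK:
    def test_dose_coefficient_is_unity(self, runner):
        space = ParameterSpace([ParameterEntry("dose", 5.0, (1.0, 20.0))])
        local = lsa_oat(runner, space)
        assert local["dose"] == pytest.approx(1.0, abs=1e-3)

    def test_low_extraction_clearance_coefficient_near_minus_one(self, runner):
        space = ParameterSpace([ParameterEntry("clint_scale", 1.0, (0.5, 2.0))])
        local = lsa_oat(runner, space)
        assert local["clint_scale"] == pytest.approx(-1.0, abs=0.1)

    def test_structurally_inert_parameter(self, runner):
        """Brain flow has no elimination pathway behind it."""
        space = ParameterSpace([ParameterEntry("flow_brain", 1.0, (0.5, 2.0))])
        local = lsa_oat(runner, space)
        assert abs(local["flow_brain"]) < 0.02


class TestPediatricScreening:
    def test_ugt_and_transit_outrank_inert_flows(self, compound, adult):
        """On a child individual, enzyme expression and GI transit dominate
        the exposure sensitivity ranking; brain perfusion is structurally
        inert for AUC."""
        from henapbpk.physiology import apply_ontogeny, scale_to_age
        child = apply_ontogeny(scale_to_age(adult, 6.5, "male"))
        runner = make_exposure_runner(compound, child, DosingRegimen(dose=2.5),
                                      metric="auc", duration=72.0,
                                      output_step=0.5)
        space = ParameterSpace([
            ParameterEntry("expr_UGT1A9", 1.0, (0.5, 1.5)),
            ParameterEntry("expr_UGT2B7", 1.0, (0.5, 1.5)),
            ParameterEntry("gfr_mlmin", child.gfr, (0.5 * child.gfr, 1.5 * child.gfr)),
            ParameterEntry("si_transit_h", 3.5, (1.75, 5.25)),
            ParameterEntry("flow_brain", 1.0, (0.5, 1.5)),
        ], seed=9)
        result = morris_screening(runner, space, r_trajectories=4)
        # normalized mu* (effects are in output units; compare relatively)
        mu = {k: v[0] for k, v in result.items()}
        assert mu["expr_UGT1A9"] > mu["flow_brain"]
        assert mu["si_transit_h"] > mu["flow_brain"]
        ranked = sorted(mu, key=mu.get, reverse=True)
        assert "expr_UGT1A9" in ranked[:2]
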