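import numpy as np
import pytest

from extempore_be.absorption import (
    GICompartment,
    SimulationConfig,
    default_fasted_physiology,
    johnson_dissolution_rate,
    precipitation_rate,
    simulate_absorption,
)
from extempore_be.dissolution import DissolutionProfile
from extempore_be.errors import ConfigurationError


class TestDefaultPhysiology:
    def test_nine_compartments_in_anatomical_order(self, physiology):
        assert len(physiology) == 9
        assert [c.name for c in physiology][:2] == ["stomach", "duodenum"]
        assert physiology[-1].name == "asc_colon"

    def test_small_intestinal_transit_about_three_point_three_hours(self, physiology):
        si = [c for c in physiology if c.region == "small_intestine"]
        assert sum(c.transit_time_h for c in si) == pytest.approx(3.3, abs=0.05)

    def test_stomach_does_not_absorb(self, physiology):
        assert physiology[0].absorption_scale_factor == 0.0
        assert not physiology[0].absorbing

    def test_colonic_scale_reduced(self, physiology):
        for c in physiology:
            if c.region == "colon":
                assert c.absorption_scale_factor == pytest.approx(0.1)


class TestJohnsonRate:
    def test_saturated_lumen_stops_dissolution(self, aml):
        assert johnson_dissolution_rate(5.0, 25e-4, aml, 1.0, 1.0) == 0.0

    def test_no_solid_no_dissolution(self, aml):
        assert johnson_dissolution_rate(0.0, 25e-4, aml, 1.0, 0.0) == 0.0

    def test_hand_computed_gastric_rate(self, aml):
        # 5 mg of 25 um particles in gastric fluid, far from saturation
        rate_mg_h = johnson_dissolution_rate(5.0, 25e-4, aml, 36.94, 0.0)
        assert rate_mg_h / 3600.0 == pytest.approx(3.10e-3, rel=2e-3)


class TestPrecipitationRate:
    def test_subsaturated_solution_is_stable(self):
        assert precipitation_rate(1.0, 100.0, 1.0, 900.0) == 0.0

    def test_infinite_precipitation_time_limit(self):
        assert precipitation_rate(10.0, 100.0, 0.01, 1e12) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_supersaturated_rate(self):
        s = 0.0168
        rate_mg_h = precipitation_rate(2 * s * 100.0, 100.0, s, 900.0)
        assert rate_mg_h / 3600.0 == pytest.approx(1.867e-3, rel=1e-3)

    def test_non_positive_mpt_rejected(self):
        with pytest.raises(ConfigurationError):
            precipitation_rate(1.0, 100.0, 1.0, 0.0)


def cat_chain(n=7, total_transit_h=3.3, radius_cm=1.5, asf=1.0):
    return [
        GICompartment(
            name=f"si{i}", volume_ml=100.0, ph=6.5,
            transit_time_h=total_transit_h / n, radius_cm=radius_cm,
            absorption_scale_factor=asf, absorbing=True,
        )
        for i in range(n)
    ]


class TestSimulateAbsorption:
    def test_zero_dose_gives_zero_trajectory(self, light_drug, physiology, light_config):
        drug = light_drug.model_copy(update={"dose_mg": 0.0})
        res = simulate_absorption(drug, physiology, light_config)
        assert res.fraction_absorbed == 0.0
        assert np.all(res.input_rate_mg_h == 0.0)

    def test_zero_permeability_absorbs_nothing(self, light_drug, physiology):
        drug = light_drug.model_copy(update={"peff_cm_s": 0.0})
        config = SimulationConfig(duration_h=96.0, output_step_h=0.2,
                                  rtol=1e-7, atol=1e-9)
        res = simulate_absorption(drug, physiology, config)
        assert res.fraction_absorbed == pytest.approx(0.0, abs=1e-9)
        # everything eventually transits out of the terminal compartment
        assert res.transited_out_mg_cumulative[-1] == pytest.approx(
            drug.dose_mg, rel=0.05)

    def test_cat_closed_form_fraction_absorbed(self, light_drug):
        # 7 equal transit compartments, predissolved dose, uniform ka:
        # Fa = 1 - (1 + ka T / 7)^-7
        chain = cat_chain()
        ka = 2 * light_drug.peff_cm_s * 3600.0 / 1.5
        config = SimulationConfig(duration_h=48.0, output_step_h=0.1,
                                  predissolved=True, rtol=1e-9, atol=1e-11)
        res = simulate_absorption(light_drug, chain, config)
        expected = 1.0 - (1.0 + ka * 3.3 / 7.0) ** -7
        assert res.fraction_absorbed == pytest.approx(expected, rel=0.01)

    def test_mass_balance_mechanistic(self, light_drug, physiology, light_config):
        res = simulate_absorption(light_drug, physiology, light_config)
        assert res.mass_balance_error_mg < 1e-6 * light_drug.dose_mg

    def test_mass_balance_tabulated(self, aml, physiology):
        from extempore_be import datasets

        config = SimulationConfig(
            duration_h=24.0, output_step_h=0.1, dissolution_mode="tabulated",
            tabulated_profiles=datasets.dissolution_profiles_for(
                "amlodipine", "tablet"),
            rtol=1e-8, atol=1e-10,
        )
        res = simulate_absorption(aml, physiology, config)
        assert res.mass_balance_error_mg < 1e-6 * aml.dose_mg

    def test_fraction_absorbed_monotone_in_permeability(
        self, light_drug, physiology, light_config
    ):
        fas = []
        for peff in (0.2e-4, 1.0e-4, 5.0e-4):
            drug = light_drug.model_copy(update={"peff_cm_s": peff})
            fas.append(simulate_absorption(drug, physiology, light_config)
                       .fraction_absorbed)
        assert fas[0] < fas[1] < fas[2]

    def test_fraction_absorbed_monotone_in_solubility(self, light_drug, physiology):
        # slow intrinsic dissolution makes solubility rate-limiting
        fas = []
        for sol in (0.001, 0.01, 0.1):
            drug = light_drug.model_copy(update={
                "ref_solubility_mg_ml": sol,
                "diffusion_coefficient_cm2_s": 1e-7,
            })
            config = SimulationConfig(duration_h=24.0, output_step_h=0.1,
                                      rtol=1e-7, atol=1e-9)
            fas.append(simulate_absorption(drug, physiology, config)
                       .fraction_absorbed)
        assert fas[0] < fas[1] < fas[2]

    def test_tabulated_instant_profile_matches_mechanistic_limit(
        self, light_drug, physiology
    ):
        instant = DissolutionProfile(
            product="instant", medium_ph=6.5,
            timepoints_min=[0.01], pct_dissolved=[100.0],
        )
        tab = SimulationConfig(
            duration_h=24.0, output_step_h=0.1, dissolution_mode="tabulated",
            tabulated_profiles={6.5: instant}, rtol=1e-8, atol=1e-10,
        )
        mech = SimulationConfig(duration_h=24.0, output_step_h=0.1,
                                predissolved=True, rtol=1e-8, atol=1e-10)
        fa_tab = simulate_absorption(light_drug, physiology, tab).fraction_absorbed
        fa_mech = simulate_absorption(light_drug, physiology, mech).fraction_absorbed
        assert fa_tab == pytest.approx(fa_mech, rel=0.01)

    def test_states_never_significantly_negative(self, light_drug, physiology, light_config):
        res = simulate_absorption(light_drug, physiology, light_config)
        floor = -1e-6 * light_drug.dose_mg
        assert res.undissolved_mg.min() >= floor
        assert res.dissolved_mg.min() >= floor
        assert res.precipitated_mg.min() >= floor

    def test_colonic_absorption_flag_blocks_distal_uptake(self, light_drug, physiology):
        config = SimulationConfig(duration_h=24.0, output_step_h=0.1,
                                  rtol=1e-7, atol=1e-9)
        with_colon = simulate_absorption(light_drug, physiology, config)
        no_colon = simulate_absorption(
            light_drug.model_copy(update={"colonic_absorption": False}),
            physiology, config)
        assert no_colon.fraction_absorbed < with_colon.fraction_absorbed
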