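"""Indicator engine: hand-computed oracles and structural invariants."""
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from croppsi.coefficients import default_coefficients
from croppsi.indicators import (
    IndicatorCalculator,
    MissingFactorError,
    agronomic_energy_input,
    compute_indicator_row,
    compute_indicators,
    economics,
    n2o_co2e,
    net_energy_yield,
    partial_ghg_emissions,
    partial_ghg_footprint,
    rice_equivalent_yield,
    total_energy_production,
)
from croppsi.simulate import default_config, generate

from conftest import make_obs, make_record

COEF = default_coefficients()


class TestRiceEquivalentYield:
    def test_single_aman_at_own_price_is_the_identity(self):
        obs = make_obs([make_record(grain_yield=2.0, crop_price=18000)])
        assert rice_equivalent_yield(obs) == pytest.approx(2.0)

    def test_price_ratio_forces_contribution(self):
        aman = make_record(grain_yield=0.0, crop_price=18000)
        mung = make_record(
            season="rabi", crop="mungbean", grain_yield=1.0, crop_price=54000
        )
        obs = make_obs([mung, aman], system="MFA")
        assert rice_equivalent_yield(obs) == pytest.approx(3.0)

    def test_hand_evaluated_decomposition(self, toy_mfa_observation):
        # 2.4 grain + 2.0 straw at a tenth of the grain price (+0.2)
        # + 0.9 t mungbean at triple the rice price (+2.7).
        assert rice_equivalent_yield(toy_mfa_observation) == pytest.approx(
            5.3, rel=1e-9
        )

    def test_invariant_under_common_price_rescaling(self, toy_mfa_observation):
        base = rice_equivalent_yield(toy_mfa_observation)
        scaled_records = [
            replace(
                r,
                crop_price=r.crop_price * 3.7,
                straw_price=r.straw_price * 3.7,
            )
            for r in toy_mfa_observation.records
        ]
        scaled = make_obs(scaled_records, system="MFA")
        assert rice_equivalent_yield(scaled) == pytest.approx(base, rel=1e-12)

    def test_nonpositive_rice_price_is_a_domain_error(self):
        obs = make_obs([make_record(grain_yield=2.0, crop_price=1.0)])
        obs.records[0].crop_price = 0.0
        with pytest.raises(ValueError, match="P_r"):
            rice_equivalent_yield(obs)


class TestEconomics:
    def test_all_zero_quantities(self):
        obs = make_obs([make_record(grain_yield=0.0, crop_price=100)])
        assert economics(obs) == (0.0, 0.0, 0.0)

    def test_gross_equals_cost_gives_zero_net(self):
        obs = make_obs(
            [make_record(grain_yield=5.0, crop_price=20000, cost_inputs=100000)]
        )
        gross, cost, net = economics(obs)
        assert gross == cost == 100000
        assert net == 0.0

    def test_hand_arithmetic_with_straw_value(self):
        obs = make_obs(
            [
                make_record(
                    grain_yield=2.4, straw_yield=2.0,
                    crop_price=20000, straw_price=2000,
                    cost_inputs=10000, cost_labor=14000, cost_landprep=6000,
                )
            ]
        )
        gross, cost, net = economics(obs)
        assert gross == pytest.approx(52000, rel=1e-12)
        assert cost == pytest.approx(30000, rel=1e-12)
        assert net == pytest.approx(22000, rel=1e-12)


class TestEnergyInput:
    def test_zero_input_system_has_zero_aei(self):
        aman = make_record(grain_yield=2.0, crop_price=18000)
        rabi = make_record(season="rabi", crop="fallow")
        obs = make_obs([rabi, aman])
        assert agronomic_energy_input(obs, COEF) == 0.0

    def test_hand_arithmetic_n_plus_labor(self):
        # 100 kg N x 60.6 MJ + 200 h x 1.96 MJ = 6.452 GJ.
        obs = make_obs(
            [
                make_record(
                    grain_yield=2.0, crop_price=18000, n_rate=100,
                    labor_total=200,
                )
            ]
        )
        assert agronomic_energy_input(obs, COEF) == pytest.approx(
            6.452, rel=1e-9
        )

    def test_linearity_doubling_inputs_doubles_aei(self, toy_mfa_observation):
        doubled = make_obs(
            [
                replace(
                    r,
                    n_rate=2 * r.n_rate, p_rate=2 * r.p_rate,
                    k_rate=2 * r.k_rate, pesticide=2 * r.pesticide,
                    fuel=2 * r.fuel, labor_total=2 * r.labor_total,
                )
                for r in toy_mfa_observation.records
            ],
            system="MFA",
        )
        assert agronomic_energy_input(doubled, COEF) == pytest.approx(
            2 * agronomic_energy_input(toy_mfa_observation, COEF), rel=1e-12
        )

    def test_missing_factor_names_the_input(self):
        table = replace(
            COEF, energy_per_input={k: v for k, v in
                                    COEF.energy_per_input.items() if k != "n"}
        )
        obs = make_obs([make_record(grain_yield=1.0, crop_price=1.0, n_rate=1)])
        with pytest.raises(MissingFactorError, match="'n'"):
            agronomic_energy_input(obs, table)


class TestEnergyProduction:
    def test_zero_yields(self):
        obs = make_obs([make_record(grain_yield=0.0, crop_price=18000)])
        assert total_energy_production(obs, COEF) == 0.0

    def test_hand_arithmetic_aman_grain(self):
        obs = make_obs([make_record(grain_yield=2.4, crop_price=18000)])
        assert total_energy_production(obs, COEF) == pytest.approx(
            35.28, rel=1e-9
        )

    def test_straw_is_excluded_from_energy_production(self):
        bare = make_obs([make_record(grain_yield=2.4, crop_price=18000)])
        strawed = make_obs(
            [make_record(grain_yield=2.4, straw_yield=3.0, crop_price=18000,
                         straw_price=1800)]
        )
        assert total_energy_production(bare, COEF) == total_energy_production(
            strawed, COEF
        )

    def test_second_crop_strictly_increases_tep(self, toy_mfa_observation):
        only_aman = make_obs([toy_mfa_observation.records[1]])
        assert total_energy_production(
            toy_mfa_observation, COEF
        ) > total_energy_production(only_aman, COEF)

    def test_missing_grain_factor_errors(self):
        table = replace(COEF, energy_grain_by_crop={"aman_rice": 14.7})
        mung = make_record(season="rabi", crop="mungbean", grain_yield=1.0,
                           crop_price=1.0)
        aman = make_record(grain_yield=1.0, crop_price=1.0)
        with pytest.raises(MissingFactorError, match="mungbean"):
            total_energy_production(make_obs([mung, aman], system="MFA"), table)


def test_net_energy_yield_is_plain_subtraction():
    assert net_energy_yield(35.28, 6.452) == pytest.approx(28.828, rel=1e-12)
    assert net_energy_yield(5.0, 5.0) == 0.0
    assert net_energy_yield(0.0, 5.0) == -5.0


class TestN2O:
    def test_zero_nitrogen(self):
        assert n2o_co2e(0.0, COEF.n2o_factors) == 0.0

    def test_tier1_hand_arithmetic(self):
        # 100 kg N: direct 1.0 + volatilized 0.1 + leached 0.225 kg N2O-N
        # = 1.325 kg N2O-N -> x 44/28 x 265 kg CO2e.
        expected = 1.325 * 44.0 / 28.0 * 265.0
        assert n2o_co2e(100.0, COEF.n2o_factors) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(551.8, abs=0.05)

    def test_linearity(self):
        f = COEF.n2o_factors
        assert n2o_co2e(2 * 37.5, f) == pytest.approx(2 * n2o_co2e(37.5, f))


class TestGhgFootprint:
    def test_zero_inputs_positive_yield_is_zero(self):
        obs = make_obs([make_record(grain_yield=2.0, crop_price=18000)])
        assert partial_ghg_footprint(obs, COEF) == 0.0

    def test_hand_arithmetic(self):
        # Emissions from 100 kg N only over 35.28 GJ of grain energy.
        obs = make_obs(
            [make_record(grain_yield=2.4, crop_price=18000, n_rate=100)]
        )
        n_only = 100 * COEF.ghg_per_input["n"] + n2o_co2e(100, COEF.n2o_factors)
        assert partial_ghg_footprint(obs, COEF) == pytest.approx(
            n_only / 35.28, rel=1e-9
        )

    def test_zero_tep_is_masked_not_infinite(self):
        obs = make_obs([make_record(grain_yield=0.0, crop_price=18000,
                                    n_rate=50)])
        assert math.isnan(partial_ghg_footprint(obs, COEF))

    def test_extra_clean_energy_dilutes_footprint(self):
        aman = make_record(grain_yield=2.4, crop_price=18000, n_rate=100)
        mung = make_record(season="rabi", crop="mungbean", grain_yield=1.0,
                           crop_price=54000)
        alone = make_obs([aman])
        diversified = make_obs([mung, aman], system="MFA")
        assert partial_ghg_footprint(diversified, COEF) < partial_ghg_footprint(
            alone, COEF
        )


class TestEfficiencyIndicators:
    def test_unity_cases(self):
        row = compute_indicator_row(
            make_obs(
                [
                    make_record(
                        grain_yield=2.4, crop_price=20000, n_rate=31,
                        cost_inputs=48000,
                    )
                ]
            ),
            COEF,
        )
        assert row["bcr"] == pytest.approx(1.0)      # gross == cost
        assert row["pnp"] == pytest.approx(35.28 / 31, rel=1e-9)

    def test_zero_denominators_are_masked(self):
        row = compute_indicator_row(
            make_obs([make_record(grain_yield=2.0, crop_price=18000)]), COEF
        )
        for name in ("energy_efficiency", "pnp", "pkp", "bcr", "hlep"):
            assert math.isnan(row[name]), name

    def test_energy_identity_links_efficiency(self, toy_mfa_observation):
        obs = make_obs(
            [
                replace(toy_mfa_observation.records[0], n_rate=15,
                        labor_total=200),
                replace(toy_mfa_observation.records[1], n_rate=31,
                        labor_total=450),
            ],
            system="MFA",
        )
        row = compute_indicator_row(obs, COEF)
        assert row["tep"] == pytest.approx(row["ney"] + row["aei"], rel=1e-12)
        assert row["tep"] / row["aei"] == pytest.approx(
            row["energy_efficiency"] + 1.0, rel=1e-12
        )


class TestVectorizedEngine:
    def test_matches_per_observation_path(self, small_survey, coef):
        from croppsi.io import frame_to_observations

        vec = compute_indicators(small_survey, coef)
        obs = compute_indicators(frame_to_observations(small_survey), coef)
        key = ["household_id", "stratum", "system"]
        vec = vec.sort_values(key, ignore_index=True)
        obs = obs.sort_values(key, ignore_index=True)
        pd.testing.assert_frame_equal(vec, obs, rtol=1e-12, atol=1e-12)

    def test_additivity_under_record_splitting(self, small_survey, coef):
        """Splitting every crop row into two half-rate rows of the same
        crop leaves every indicator unchanged."""
        halves = small_survey.copy()
        numeric = halves.select_dtypes("number").columns
        # Prices are intensive; halve only the extensive quantities.
        extensive = [c for c in numeric if "price" not in c]
        halves[extensive] = halves[extensive] / 2.0
        split = pd.concat([halves, halves], ignore_index=True)
        a = compute_indicators(small_survey, coef)
        b = compute_indicators(split, coef)
        key = ["household_id", "stratum", "system"]
        pd.testing.assert_frame_equal(
            a.sort_values(key, ignore_index=True),
            b.sort_values(key, ignore_index=True),
            rtol=1e-9,
        )

    def test_transformer_wrapper(self, small_survey, coef):
        calc = IndicatorCalculator(coefficients=coef)
        out = calc.fit_transform(small_survey)
        direct = compute_indicators(small_survey, coef)
        pd.testing.assert_frame_equal(out, direct)

    def test_sklearn_params_round_trip(self, coef):
        calc = IndicatorCalculator(coefficients=coef)
        assert calc.get_params()["coefficients"] is coef
        calc.set_params(coefficients=None)
        assert calc.get_params()["coefficients"] is None
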