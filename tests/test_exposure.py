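"""Population simulation, dietary exposures and the BMI energy-balance rule."""

import numpy as np
import pandas as pd
import pytest

from fiscalfood import (
    FoodGroupProfile,
    Stratum,
    build_population,
    delta_bmi,
    dietary_exposures,
    scale_strata,
    scenario_exposure_table,
)
from fiscalfood.errors import DomainError, MissingCoefficientError, StructuralError


def _strata(counts, sd=0.0):
    return [
        Stratum(age_band=band, sex="male", population=c,
                height_mean=1.6 + 0.1 * i, height_sd=sd,
                weight_mean=70.0 + i, weight_sd=sd)
        for i, (band, c) in enumerate(counts)
    ]


class TestBuildPopulation:
    def test_exact_proportional_allocation(self):
        strata = _strata([("25-29", 600), ("30-34", 400)])
        pop = build_population(1000, strata, seed=0)
        counts = pop.frame["age_band"].value_counts()
        assert counts["25-29"] == 600 and counts["30-34"] == 400

    def test_sd_zero_gives_degenerate_anthropometry(self):
        strata = _strata([("25-29", 50)])
        pop = build_population(50, strata, seed=0)
        assert pop.frame["height"].nunique() == 1
        assert pop.frame["weight"].nunique() == 1

    def test_same_seed_is_identical(self):
        strata = _strata([("25-29", 40), ("30-34", 60)], sd=0.05)
        a = build_population(100, strata, seed=3)
        b = build_population(100, strata, seed=3)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_count_mismatch_raises(self):
        with pytest.raises(StructuralError):
            build_population(99, _strata([("25-29", 60), ("30-34", 50)]), seed=0)

    def test_bmi_consistent_with_height_and_weight(self):
        strata = _strata([("25-29", 200)], sd=0.06)
        pop = build_population(200, strata, seed=1)
        np.testing.assert_allclose(
            pop.frame["bmi"], pop.frame["weight"] / pop.frame["height"] ** 2
        )

    def test_scale_strata_preserves_structure(self):
        strata = _strata([("25-29", 600_000), ("30-34", 400_000)])
        scaled = scale_strata(strata, 1000)
        assert [s.population for s in scaled] == [600, 400]


class TestDietaryExposures:
    PROFILES = [
        FoodGroupProfile("a", price=1.0, quantity=0, sugar_content=50.0,
                         sfa_content=10.0, energy_density=500.0),
        FoodGroupProfile("b", price=1.0, quantity=0, sfa_content=40.0,
                         energy_density=1000.0),
        FoodGroupProfile("ssb", price=1.0, quantity=0, energy_density=180.0),
    ]

    def test_single_group_sugar(self):
        exp = dietary_exposures({"a": 100.0}, self.PROFILES)
        assert exp["sugar"] == pytest.approx(50.0)
        assert exp["energy"] == pytest.approx(500.0)

    def test_empty_basket_all_zero(self):
        exp = dietary_exposures({}, self.PROFILES)
        assert all(v == 0.0 for v in exp.values())

    def test_sfa_sums_across_groups(self):
        # 200 g at 10/100 g + 50 g at 40/100 g = 20 + 20 = 40 g/day
        exp = dietary_exposures({"a": 200.0, "b": 50.0}, self.PROFILES)
        assert exp["sfa"] == pytest.approx(40.0)

    def test_ssb_exposure_is_group_quantity(self):
        exp = dietary_exposures({"ssb": 130.0}, self.PROFILES)
        assert exp["ssb"] == pytest.approx(130.0)

    def test_missing_profile_raises(self):
        with pytest.raises(MissingCoefficientError):
            dietary_exposures({"zzz": 1.0}, self.PROFILES)


class TestDeltaBmi:
    @pytest.mark.parametrize("de,h,rho,expected", [
        (0.0, 1.7, 94.0, 0.0),
        (-94.0, 1.3, 94.0, -1.0 / 1.69),
        (-188.0, 1.6, 94.0, -0.78125),
    ])
    def test_steady_state_rule(self, de, h, rho, expected):
        assert delta_bmi(de, h, rho) == pytest.approx(expected)

    def test_rho_must_be_positive(self):
        with pytest.raises(DomainError):
            delta_bmi(-100.0, 1.7, rho=0.0)

    def test_linear_in_energy_and_inverse_square_in_height(self):
        d1 = delta_bmi(-100.0, 1.5)
        assert delta_bmi(-200.0, 1.5) == pytest.approx(2 * d1)
        assert delta_bmi(-100.0, 2.1) == pytest.approx(d1 * (1.5 / 2.1) ** 2)


class TestScenarioExposureTable:
    PROFILES = [
        FoodGroupProfile("a", price=1.0, quantity=0, sugar_content=50.0,
                         energy_density=1880.0),
    ]

    def test_identity_counterfactual_gives_zero_changes(self):
        strata = _strata([("25-29", 20)])
        pop = build_population(20, strata, seed=0)
        deltas, _ = scenario_exposure_table(pop, {"a": 100.0}, {"a": 100.0}, self.PROFILES)
        assert all(d.percent_change == 0.0 for d in deltas)

    def test_single_person_bmi_shift(self):
        # energy -94 kJ/day at height ~1.3 with rho 94 shifts BMI by -1/h^2
        strata = [Stratum("25-29", "male", 1, height_mean=1.3, height_sd=0.0,
                          weight_mean=25 * 1.69, weight_sd=0.0)]
        pop = build_population(1, strata, seed=0)
        base = {"a": 100.0}
        cf = {"a": 95.0}  # -5 g at 1880 kJ/100g = -94 kJ/day
        deltas, per_person = scenario_exposure_table(pop, base, cf, self.PROFILES, rho=94.0)
        bmi = next(d for d in deltas if d.risk_factor == "bmi")
        assert per_person["base_bmi"].iloc[0] == pytest.approx(25.0)
        # delta_BMI = (-94/94) / 1.3^2 = -1/1.69 kg/m2
        assert bmi.counterfactual == pytest.approx(25.0 - 1.0 / 1.69)

    def test_percent_change_invariant_to_population_size(self):
        base, cf = {"a": 100.0}, {"a": 80.0}
        out = []
        for n in (100, 10_000):
            strata = _strata([("25-29", int(0.6 * n)), ("30-34", int(0.4 * n))])
            pop = build_population(n, strata, seed=0)
            deltas, _ = scenario_exposure_table(pop, base, cf, self.PROFILES)
            out.append({d.risk_factor: d.percent_change for d in deltas})
        assert out[0]["sugar"] == pytest.approx(out[1]["sugar"])
        assert out[0]["sugar"] == pytest.approx(-20.0)

    def test_bmi_floor_binds(self):
        strata = [Stratum("25-29", "male", 1, height_mean=1.5, height_sd=0.0,
                          weight_mean=16 * 2.25, weight_sd=0.0)]
        pop = build_population(1, strata, seed=0)
        deltas, _ = scenario_exposure_table(
            pop, {"a": 1000.0}, {"a": 0.0}, self.PROFILES, bmi_floor=15.0
        )
        bmi = next(d for d in deltas if d.risk_factor == "bmi")
        assert bmi.counterfactual == pytest.approx(15.0)

    def test_counterfactual_dietary_exposures_nonnegative(self):
        strata = _strata([("25-29", 10)])
        pop = build_population(10, strata, seed=0)
        _, per_person = scenario_exposure_table(pop, {"a": 50.0}, {"a": 0.0}, self.PROFILES)
        for rf in ("sugar", "ssb", "sfa", "tfa"):
            assert (per_person[f"cf_{rf}"] >= 0).all()
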