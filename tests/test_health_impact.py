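"""RR scaling, population impact fractions and averted burden."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiscalfood import (
    RelativeRisk,
    Stratum,
    averted_burden,
    combine_pifs,
    incidence_percent_change,
    population_impact_fraction,
    rr_at_exposure,
)
from fiscalfood.errors import DomainError, MissingCoefficientError, StructuralError
from fiscalfood.health_impact import bmi_excess


def brute_force_pif(baseline, counterfactual, rr_value, increment):
    """Independent scalar-loop oracle for the PIF equation."""
    num = sum(math.exp(math.log(rr_value) * m / increment) for m in counterfactual)
    den = sum(math.exp(math.log(rr_value) * m / increment) for m in baseline)
    return 1.0 - num / den


RR = RelativeRisk("sugar", "type_2_diabetes", 1.2, 100.0)


class TestRrAtExposure:
    def test_null_exposure_gives_one(self):
        assert rr_at_exposure(RR, 0.0) == 1.0

    def test_one_increment_returns_point_rr_exactly(self):
        assert rr_at_exposure(RR, 100.0) == pytest.approx(1.2, abs=1e-15)

    def test_half_increment(self):
        assert rr_at_exposure(RR, 50.0) == pytest.approx(1.0954451150103321, abs=1e-12)

    def test_vectorised(self):
        out = rr_at_exposure(RR, [0.0, 100.0])
        np.testing.assert_allclose(out, [1.0, 1.2])


class TestPopulationImpactFraction:
    def test_identity_is_zero(self):
        assert population_impact_fraction([10, 20, 30], [10, 20, 30], RR) == 0.0

    def test_two_person_example(self):
        # exact value computed with the independent brute-force oracle
        pif = population_impact_fraction([100, 200], [80, 160], RR)
        assert pif == pytest.approx(0.05463948830342946, abs=1e-12)
        assert pif == pytest.approx(brute_force_pif([100, 200], [80, 160], 1.2, 100.0))

    def test_total_removal_is_protective(self):
        assert population_impact_fraction([100, 50], [0, 0], RR) > 0

    def test_empty_or_mismatched_raises(self):
        with pytest.raises(StructuralError):
            population_impact_fraction([], [], RR)
        with pytest.raises(StructuralError):
            population_impact_fraction([1, 2], [1], RR)

    def test_exposure_increase_gives_negative_pif(self):
        assert population_impact_fraction([100], [150], RR) < 0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 300), min_size=1, max_size=20),
           st.floats(0.01, 0.99), st.floats(1.01, 3.0))
    def test_matches_brute_force_oracle(self, baseline, shrink, rr_value):
        rr = RelativeRisk("x", "d", rr_value, 100.0)
        cf = [m * shrink for m in baseline]
        got = population_impact_fraction(baseline, cf, rr)
        want = brute_force_pif(baseline, cf, rr_value, 100.0)
        assert got == pytest.approx(want, abs=1e-13)

    def test_monotone_in_counterfactual_exposure(self):
        base = [100.0, 150.0, 80.0]
        lower = population_impact_fraction(base, [90.0, 150.0, 80.0], RR)
        lower_more = population_impact_fraction(base, [50.0, 150.0, 80.0], RR)
        assert lower_more > lower > 0

    def test_invariant_to_duplicating_population(self):
        base, cf = [100.0, 50.0], [70.0, 40.0]
        single = population_impact_fraction(base, cf, RR)
        doubled = population_impact_fraction(base * 2, cf * 2, RR)
        assert doubled == pytest.approx(single, abs=1e-15)


class TestCombinePifs:
    @pytest.mark.parametrize("pifs,expected", [
        ([0.0], 0.0),
        ([0.1, 0.2], 0.28),
        ([0.37, 0.0], 0.37),
    ])
    def test_multiplicative_combination(self, pifs, expected):
        assert combine_pifs(pifs) == pytest.approx(expected)

    def test_order_invariant(self):
        assert combine_pifs([0.1, 0.25, -0.05]) == pytest.approx(
            combine_pifs([-0.05, 0.1, 0.25]))

    def test_rejects_pif_above_one(self):
        with pytest.raises(DomainError):
            combine_pifs([1.2])


def _stratum(band, pop, inc, daly):
    return Stratum(band, "male", pop,
                   incidence={"d": inc}, daly={"d": daly})


class TestAvertedBurden:
    def test_zero_pif_everywhere(self):
        strata = [_stratum("25-29", 1000, 100, 500)]
        b = averted_burden({("25-29", "male"): 0.0}, strata, "d")
        assert b.averted_cases == 0.0 and b.averted_dalys == 0.0

    def test_single_stratum_dalys(self):
        # 0.01 x 2000/100k x 500,000 = 100 DALYs
        strata = [_stratum("25-29", 500_000, 0.0, 2000.0)]
        b = averted_burden({("25-29", "male"): 0.01}, strata, "d")
        assert b.averted_dalys == pytest.approx(100.0)

    def test_totals_are_sums_over_strata(self):
        strata = [_stratum("25-29", 500_000, 100, 1000),
                  _stratum("30-34", 500_000, 100, 1000)]
        pifs = {("25-29", "male"): 0.01, ("30-34", "male"): 0.01}
        b = averted_burden(pifs, strata, "d")
        assert b.averted_dalys == pytest.approx(sum(b.averted_dalys_by_stratum.values()))
        assert b.averted_dalys == pytest.approx(100.0)

    def test_missing_rate_raises(self):
        s = Stratum("25-29", "male", 100, incidence={}, daly={})
        with pytest.raises(MissingCoefficientError):
            averted_burden({("25-29", "male"): 0.1}, [s], "d")


class TestIncidencePercentChange:
    def test_zero_pif_is_zero(self):
        strata = [_stratum("25-29", 1000, 50, 0)]
        assert incidence_percent_change({("25-29", "male"): 0.0}, strata, "d") == 0.0

    def test_uniform_pif_passes_through(self):
        strata = [_stratum("25-29", 1000, 50, 0), _stratum("30-34", 500, 80, 0)]
        pifs = {s.key: 0.0252 for s in strata}
        assert incidence_percent_change(pifs, strata, "d") == pytest.approx(-2.52)

    def test_weighted_mean_of_heterogeneous_pifs(self):
        # equal incidence mass in both strata -> plain mean of (2%, 1%)
        strata = [_stratum("25-29", 1000, 100, 0), _stratum("30-34", 1000, 100, 0)]
        pifs = {("25-29", "male"): 0.02, ("30-34", "male"): 0.01}
        assert incidence_percent_change(pifs, strata, "d") == pytest.approx(-1.5)

    def test_zero_total_incidence_raises(self):
        strata = [_stratum("25-29", 1000, 0.0, 0)]
        with pytest.raises(DomainError):
            incidence_percent_change({("25-29", "male"): 0.1}, strata, "d")


class TestBmiExcess:
    def test_floors_at_zero_below_tmrel(self):
        np.testing.assert_allclose(bmi_excess([20.0, 22.0, 27.0]), [0.0, 0.0, 5.0])
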