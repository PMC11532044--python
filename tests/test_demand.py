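"""Demand response: price changes, elasticity rule, waste, AME scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiscalfood import (
    ElasticityMatrix,
    FoodGroupProfile,
    HouseholdRecord,
    Member,
    TaxScenario,
    adjust_for_waste,
    ame_units,
    apply_tax_scenario,
    default_ame_table,
    per_ame_intake,
    price_change,
)
from fiscalfood.errors import DomainError, MissingCoefficientError, StructuralError


def _profile(name, quantity=100.0, price=1000.0, **kw):
    return FoodGroupProfile(name=name, price=price, quantity=quantity, **kw)


class TestPriceChange:
    @pytest.mark.parametrize("rate,pass_through,expected", [
        (0.30, 1.0, 0.30),
        (0.30, 0.5, 0.15),
        (0.0, 1.0, 0.0),
    ])
    def test_pass_through_scaling(self, rate, pass_through, expected):
        scen = TaxScenario("t", {"a": rate}, pass_through=pass_through)
        assert price_change(scen, "a") == pytest.approx(expected)

    def test_untaxed_group_is_zero(self):
        scen = TaxScenario("t", {"a": 0.3})
        assert price_change(scen, "b") == 0.0

    def test_unknown_group_raises(self):
        scen = TaxScenario("t", {"a": 0.3})
        with pytest.raises(MissingCoefficientError):
            price_change(scen, "zzz", groups=["a", "b"])


class TestApplyTaxScenario:
    def test_no_tax_is_exact_fixed_point(self):
        basket = [_profile("a"), _profile("b", quantity=55.0)]
        em = ElasticityMatrix(["a", "b"], [[-1.0, 0.2], [0.0, -0.5]])
        out = apply_tax_scenario(basket, em, TaxScenario("none", {}))
        assert [p.quantity for p in out] == [p.quantity for p in basket]
        assert [p.price for p in out] == [p.price for p in basket]

    def test_single_group_linear_rule(self):
        basket = [_profile("a", quantity=200.0)]
        em = ElasticityMatrix(["a"], [[-0.5]])
        out = apply_tax_scenario(basket, em, TaxScenario("t", {"a": 0.30}))
        assert out[0].quantity == pytest.approx(200.0 * (1 - 0.15))
        assert out[0].price == pytest.approx(1000.0 * 1.30)

    def test_two_group_cross_response(self):
        # hand evaluation: dQ1/Q1 = 0.2*0.1 = +2%, dQ2/Q2 = -0.5*0.1 = -5%
        basket = [_profile("a", 100.0), _profile("b", 100.0)]
        em = ElasticityMatrix(["a", "b"], [[-1.0, 0.2], [0.0, -0.5]])
        out = apply_tax_scenario(basket, em, TaxScenario("t", {"b": 0.10}))
        assert out[0].quantity == pytest.approx(102.0)
        assert out[1].quantity == pytest.approx(95.0)

    def test_quantity_floored_at_zero(self):
        basket = [_profile("a", 10.0)]
        em = ElasticityMatrix(["a"], [[-5.0]])
        out = apply_tax_scenario(basket, em, TaxScenario("t", {"a": 0.5}))
        assert out[0].quantity == 0.0

    def test_dimension_mismatch_raises(self):
        basket = [_profile("a")]
        em = ElasticityMatrix(["a", "b"], [[-1.0, 0.0], [0.0, -1.0]])
        with pytest.raises(StructuralError):
            apply_tax_scenario(basket, em, TaxScenario("t", {"a": 0.1}))

    @settings(max_examples=50, deadline=None)
    @given(rate=st.floats(0.0, 0.2), own=st.floats(-0.9, -0.1), cross=st.floats(-0.05, 0.05))
    def test_response_linear_in_tax_rate(self, rate, own, cross):
        basket = [_profile("a", 100.0), _profile("b", 100.0)]
        em = ElasticityMatrix(["a", "b"], [[own, cross], [cross, own]])
        once = apply_tax_scenario(basket, em, TaxScenario("t", {"a": rate}))
        twice = apply_tax_scenario(basket, em, TaxScenario("t", {"a": 2 * rate}))
        d1 = once[1].quantity - 100.0
        d2 = twice[1].quantity - 100.0
        assert d2 == pytest.approx(2 * d1, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(rate=st.floats(0.0, 0.5))
    def test_diagonal_matrix_changes_only_taxed_groups(self, rate):
        basket = [_profile("a", 80.0), _profile("b", 90.0), _profile("c", 100.0)]
        em = ElasticityMatrix(["a", "b", "c"], np.diag([-0.4, -0.5, -0.6]))
        out = apply_tax_scenario(basket, em, TaxScenario("t", {"b": rate}))
        assert out[0].quantity == 80.0
        assert out[2].quantity == 100.0
        assert out[1].quantity <= 90.0

    def test_loglog_variant_close_to_linear_for_small_rates(self):
        basket = [_profile("a", 100.0)]
        em = ElasticityMatrix(["a"], [[-0.5]])
        lin = apply_tax_scenario(basket, em, TaxScenario("t", {"a": 0.01}))
        log = apply_tax_scenario(basket, em, TaxScenario("t", {"a": 0.01}), response="loglog")
        assert log[0].quantity == pytest.approx(lin[0].quantity, rel=1e-4)


class TestWasteAndAme:
    @pytest.mark.parametrize("q,w,expected", [(100, 0.0, 100), (100, 0.25, 75), (0, 0.5, 0)])
    def test_waste_adjustment(self, q, w, expected):
        assert adjust_for_waste(q, w) == pytest.approx(expected)

    def test_waste_fraction_out_of_range(self):
        with pytest.raises(DomainError):
            adjust_for_waste(100, 1.0)

    def test_reference_male_is_exactly_one(self):
        table = default_ame_table()
        assert ame_units([Member(25, "male")], table) == 1.0
        assert ame_units([Member(25, "male"), Member(25, "male")], table) == 2.0

    def test_ame_units_sum_supplied_coefficients(self):
        table = default_ame_table()
        # female aged 30 carries 0.8 in the packaged table
        assert ame_units([Member(25, "male"), Member(30, "female")], table) == pytest.approx(1.8)

    def test_missing_coefficient_raises(self):
        table = default_ame_table()
        with pytest.raises(MissingCoefficientError):
            ame_units([Member(25, "other")], table)

    @pytest.mark.parametrize("q,w,n_ref_males,expected", [
        (200.0, 0.0, 2, 100.0),
        (200.0, 0.5, 1, 100.0),
    ])
    def test_per_ame_intake(self, q, w, n_ref_males, expected):
        members = tuple(Member(25, "male") for _ in range(n_ref_males))
        record = HouseholdRecord("h1", members, {"g": q})
        intake = per_ame_intake(record, default_ame_table(), {"g": w})
        assert intake["g"] == pytest.approx(expected)

    def test_per_ame_intake_custom_coefficients(self):
        # 1.0 + 0.5 = 1.5 AME units; 150 g at 20% waste -> 150*0.8/1.5 = 80
        from fiscalfood.demand import AmeCoefficientTable
        table = AmeCoefficientTable.from_rows([
            {"age_lo": 0, "age_hi": 17, "male": 0.5, "female": 0.5},
            {"age_lo": 18, "age_hi": 120, "male": 1.0, "female": 1.0},
        ])
        record = HouseholdRecord("h3", (Member(25, "male"), Member(10, "female")),
                                 {"g": 150.0})
        assert per_ame_intake(record, table, {"g": 0.2})["g"] == pytest.approx(80.0)

    def test_per_ame_intake_fractional_units(self):
        # male 25 (1.0) + female 30 (0.8) = 1.8 AME; 150 g at 20% waste -> 66.67
        record = HouseholdRecord("h2", (Member(25, "male"), Member(30, "female")),
                                 {"g": 150.0})
        intake = per_ame_intake(record, default_ame_table(), {"g": 0.2})
        assert intake["g"] == pytest.approx(150.0 * 0.8 / 1.8)
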