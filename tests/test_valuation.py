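"""Coefficient assembly, carbon chain, coffee economics and the ESV sums."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_area_table, random_coefficient_table
from esval.landcover import AreaTable
from esval.valuation import (
    CO2_PER_TONNE_CARBON,
    CarbonProfile,
    ServiceCoefficientTable,
    ServiceFunction,
    ValueTransferRecord,
    adjust_transferred_value,
    assemble_coefficient_table,
    carbon_sequestration_value,
    carbon_stock_to_co2,
    coffee_npv,
    esv_by_class,
    esv_by_function,
    esv_total,
)


class TestAdjustTransferredValue:
    def test_identity_factor(self):
        assert adjust_transferred_value(123.4, 1.0) == 123.4

    @pytest.mark.parametrize(
        "original, adjusted",
        [(68.5, 84.31), (839.98, 1101.62)],
    )
    def test_published_original_adjusted_pairs(self, original, adjusted):
        factor = adjusted / original
        assert adjust_transferred_value(original, factor) == pytest.approx(adjusted)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_transferred_value(-1.0, 1.0)
        with pytest.raises(ValueError):
            adjust_transferred_value(1.0, -0.5)

    def test_record_validates_rounded_adjusted_value(self):
        fn = ServiceFunction("erosion_control", "regulating")
        rec = ValueTransferRecord(1, fn, 68.5, 84.31 / 68.5, adjusted_value=84.31)
        assert rec.adjusted_value == 84.31
        with pytest.raises(ValueError, match="0.5%"):
            ValueTransferRecord(1, fn, 68.5, 1.0, adjusted_value=84.31)


class TestCarbonChain:
    def test_zero_stock(self):
        assert carbon_stock_to_co2(0.0) == 0.0

    @pytest.mark.parametrize(
        "stock, co2_2dp",
        [(461.0, 1690.33), (246.5, 903.83), (279.5, 1024.83), (396.0, 1452.00)],
    )
    def test_molar_ratio_reproduces_published_co2(self, stock, co2_2dp):
        assert round(carbon_stock_to_co2(stock), 2) == pytest.approx(co2_2dp)

    def test_negative_stock_rejected(self):
        with pytest.raises(ValueError):
            carbon_stock_to_co2(-1.0)

    @pytest.mark.parametrize(
        "stock, value_2dp",
        [(461.0, 2484.79), (279.5, 1506.50)],
    )
    def test_sequestration_value_at_published_scc(self, stock, value_2dp):
        prof = CarbonProfile(class_code=1, carbon_stock=stock, scc=1.47)
        assert round(carbon_sequestration_value(prof), 2) == pytest.approx(value_2dp, abs=0.011)

    def test_zero_scc_gives_zero(self):
        prof = CarbonProfile(class_code=1, carbon_stock=500.0, scc=0.0)
        assert carbon_sequestration_value(prof) == 0.0

    def test_value_monotone_in_stock(self):
        stocks = np.linspace(0, 500, 20)
        values = [
            carbon_sequestration_value(CarbonProfile(1, s, scc=1.47)) for s in stocks
        ]
        assert all(b > a for a, b in zip(values, values[1:]))
        # closed form
        assert values[-1] == pytest.approx(500 * CO2_PER_TONNE_CARBON * 1.47)

    def test_inconsistent_co2_equivalent_rejected(self):
        with pytest.raises(ValueError, match="44/12"):
            CarbonProfile(class_code=1, carbon_stock=461.0, scc=1.47, co2_equivalent=1600.0)


class TestCoffeeNpv:
    def test_full_cost_fraction_gives_zero(self):
        assert coffee_npv(0.84, 4685.0, 1.0) == 0.0

    def test_published_inputs(self):
        assert coffee_npv(0.84, 4685.0, 0.13) == pytest.approx(0.84 * 4685.0 * 0.87)

    def test_zero_cost_identity(self):
        assert coffee_npv(1.0, 1000.0, 0.0) == 1000.0

    def test_cost_fraction_above_one_rejected(self):
        with pytest.raises(ValueError, match="cost fraction"):
            coffee_npv(1.0, 1000.0, 1.5)


class TestAssembleCoefficientTable:
    def test_empty_inputs_give_empty_table(self):
        table = assemble_coefficient_table()
        assert table.classes == []
        assert table.class_total(1) == 0.0

    def test_supporting_subtotal_from_function_entries(self, coefficients):
        # remnant forest: nutrient cycling + soil formation + pollination + habitat
        assert coefficients.category_subtotal(1, "supporting") == pytest.approx(2829.30)

    def test_regulating_subtotal_wetland(self, coefficients):
        assert coefficients.category_subtotal(5, "regulating") == pytest.approx(5063.90)

    def test_carbon_profiles_enter_as_climate_regulation(self):
        prof = CarbonProfile(class_code=3, carbon_stock=100.0, scc=2.0)
        table = assemble_coefficient_table(carbon=[prof])
        assert table.value(3, "climate_regulation") == pytest.approx(100 * 44 / 12 * 2.0)
        assert table.category_subtotal(3, "regulating") == table.value(3, "climate_regulation")

    def test_union_of_all_three_sources(self):
        fn = ServiceFunction("pollination", "supporting")
        rec = ValueTransferRecord(1, fn, 100.0, 1.5)
        prof = CarbonProfile(class_code=1, carbon_stock=12.0, scc=1.0)
        coffee = (1, ServiceFunction("coffee_production", "provisioning"), 3423.8)
        table = assemble_coefficient_table(records=[rec], carbon=[prof], extra=[coffee])
        assert table.class_total(1) == pytest.approx(150.0 + 44.0 + 3423.8)

    def test_duplicate_pair_listed_in_error(self):
        fn = ServiceFunction("pollination", "supporting")
        recs = [ValueTransferRecord(1, fn, 100.0, 1.0), ValueTransferRecord(1, fn, 5.0, 1.0)]
        with pytest.raises(ValueError, match="pollination"):
            assemble_coefficient_table(records=recs)

    def test_packaged_raw_records_load_and_validate(self):
        from esval import datasets

        records = datasets.load_value_transfer_records()
        assert len(records) > 40
        assert all(r.adjusted_value >= r.original_value * 0.9 for r in records)


class TestEsvSums:
    def test_zero_area_gives_zero_value(self):
        vc = ServiceCoefficientTable(
            pd.DataFrame([{"class_code": 1, "function": "f", "category": "supporting",
                           "value": 100.0}])
        )
        areas = AreaTable(entries={1: 0.0})
        assert esv_by_class(areas, vc)[1] == 0.0

    def test_published_class_category_products(self, coefficients, valuation_areas):
        rep = esv_total(valuation_areas, coefficients)
        # remnant forest supporting and wetland cultural, in million USD
        assert rep.by_class_category[(1, "supporting")] / 1e6 == pytest.approx(415.708, abs=5e-3)
        assert rep.by_class_category[(5, "cultural")] / 1e6 == pytest.approx(52.387, abs=5e-3)

    def test_function_absent_everywhere_is_zero(self, coefficients, valuation_areas):
        assert esv_by_function(valuation_areas, coefficients).get("no_such_service", 0.0) == 0.0

    def test_missing_area_named_in_error(self, coefficients):
        areas = AreaTable(entries={1: 10.0})
        with pytest.raises(ValueError, match=r"\[2"):
            esv_by_class(areas, coefficients)

    def test_marginal_consistency_over_random_instances(self):
        """sum_k ESV_k = sum_f ESV_f = ESV for 200 random area/coefficient draws."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            vc = random_coefficient_table(rng, n_classes=int(rng.integers(1, 5)),
                                          n_functions=int(rng.integers(1, 6)))
            areas = random_area_table(rng, n_classes=4)
            rep = esv_total(areas, vc)
            assert sum(rep.by_class.values()) == pytest.approx(rep.total, rel=1e-9)
            assert sum(rep.by_function.values()) == pytest.approx(rep.total, rel=1e-9)

    def test_agrees_with_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vc = random_coefficient_table(rng)
            areas = random_area_table(rng)
            brute = sum(
                areas.area(k) * vc.value(k, f)
                for k in vc.classes
                for f in vc.functions
            )
            assert esv_total(areas, vc).total == pytest.approx(brute, rel=1e-9)

    def test_bilinearity_in_areas_and_coefficients(self, coefficients, valuation_areas):
        base = esv_total(valuation_areas, coefficients).total
        doubled_areas = AreaTable(
            entries={k: 2 * v for k, v in valuation_areas.entries.items()}
        )
        assert esv_total(doubled_areas, coefficients).total == pytest.approx(2 * base, rel=1e-12)
        scaled_vc = ServiceCoefficientTable(
            coefficients.frame.assign(value=coefficients.frame["value"] * 3.0)
        )
        assert esv_total(valuation_areas, scaled_vc).total == pytest.approx(3 * base, rel=1e-12)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ServiceCoefficientTable(
                pd.DataFrame([{"class_code": 1, "function": "f",
                               "category": "supporting", "value": -5.0}])
            )
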