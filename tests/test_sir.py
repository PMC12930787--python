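"""Risk-day tabulation, expected counts and the standardized infection
ratio."""

import pytest

from neosurv.cohort import ValidationError
from neosurv.eligibility import build_windows
from neosurv.sir import (
    ReferenceRates,
    UnitSirAggregate,
    aggregate_reference,
    band_index,
    build_unit_sir_aggregate,
    compute_sir,
    expected_infections,
    standardized_infection_ratio,
    tabulate_risk_days,
)
from neosurv.simulate import SimulationConfig, generate_with_truth

from conftest import make_patient, make_stay


class TestRiskDays:
    def test_one_patient_counting(self):
        # 600 g infant observed days of life 1..20 under bands 1-7/8-28/29+
        patient = make_patient(birth_weight=600, los=20)
        from neosurv.eligibility import compute_surveillance_window
        window = compute_surveillance_window(patient, [make_stay(end=20)])
        table = tabulate_risk_days({"P1": window}, [patient],
                                   band_edges=(1, 8, 29))
        assert table == {("500-999 g", 0): 7, ("500-999 g", 1): 13}

    def test_empty_cohort_all_cells_zero(self):
        assert tabulate_risk_days({}, [], band_edges=(1, 8, 29)) == {}

    def test_cell_sums_conserve_patient_days(self):
        cohort, _ = generate_with_truth(SimulationConfig(n_patients=40,
                                                         seed=31))
        windows = build_windows(cohort)
        table = tabulate_risk_days(windows, cohort.patients)
        total = sum(w.patient_days for w in windows.values() if w.included)
        assert sum(table.values()) == total

    def test_band_edges_must_start_at_one(self):
        with pytest.raises(ValidationError):
            tabulate_risk_days({}, [], band_edges=(2, 8))

    def test_band_index_partition(self):
        edges = (1, 4, 8, 15, 29)
        assert [band_index(d, edges) for d in (1, 3, 4, 7, 8, 14, 15, 28,
                                               29, 200)] == \
            [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]


class TestExpected:
    def test_uniform_rate_linearity(self):
        risk = {("500-999 g", 0): 2000, ("1000-1499 g", 1): 3000}
        rates = {cell: 0.002 for cell in risk}
        assert expected_infections(risk, rates) == pytest.approx(10.0)

    def test_zero_rates_zero_expected(self):
        risk = {("500-999 g", 0): 2000}
        assert expected_infections(risk, {("500-999 g", 0): 0.0}) == 0.0

    def test_two_cell_hand_tally(self):
        risk = {("<500 g", 0): 100, (">=1500 g", 2): 400}
        rates = {("<500 g", 0): 0.01, (">=1500 g", 2): 0.005}
        assert expected_infections(risk, rates) == pytest.approx(
            100 * 0.01 + 400 * 0.005)

    def test_occupied_cell_missing_from_reference_is_error(self):
        with pytest.raises(ValidationError, match="500-999 g"):
            expected_infections({("500-999 g", 0): 10}, {})


class TestSir:
    def test_observed_equals_expected_gives_exactly_one(self):
        assert standardized_infection_ratio(10, 10.0).sir == 1.0

    def test_zero_observed(self):
        assert standardized_infection_ratio(0, 4.0).sir == 0.0

    def test_above_one(self):
        assert standardized_infection_ratio(6, 4.0).sir == 1.5

    def test_incalculable_when_expected_zero(self):
        result = standardized_infection_ratio(3, 0.0)
        assert result.sir is None
        assert result.observed == 3
        assert result.warnings

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            standardized_infection_ratio(-1, 2.0)

    def test_monotone_in_observed_and_expected(self):
        base = standardized_infection_ratio(5, 5.0).sir
        assert standardized_infection_ratio(6, 5.0).sir > base
        assert standardized_infection_ratio(5, 6.0).sir < base


class TestReferencePooling:
    def unit(self, seed):
        cohort, _ = generate_with_truth(SimulationConfig(n_patients=40,
                                                         seed=seed))
        windows = build_windows(cohort)
        from neosurv.classify import classify_cohort
        from neosurv.config import DefinitionsConfig, \
            default_organism_catalog
        infections, _ = classify_cohort(
            cohort, windows, DefinitionsConfig(),
            default_organism_catalog())
        included = [p for p in cohort.patients
                    if windows[p.patient_id].included]
        return build_unit_sir_aggregate(included, windows, infections)

    def test_single_unit_reference_is_own_rates(self):
        unit = self.unit(3)
        ref = aggregate_reference([unit])
        for cell, days in unit.patient_days.items():
            observed = unit.observed["all"].get(cell, 0)
            assert ref.rates["all"][cell] == pytest.approx(observed / days)

    def test_equal_denominators_pool_to_mean_rate(self):
        cell = ("500-999 g", 0)
        u1 = UnitSirAggregate((1, 8), {cell: 1000}, {"all": {cell: 4}})
        u2 = UnitSirAggregate((1, 8), {cell: 1000}, {"all": {cell: 8}})
        ref = aggregate_reference([u1, u2])
        assert ref.rates["all"][cell] == pytest.approx(
            (4 / 1000 + 8 / 1000) / 2)

    def test_self_benchmark_gives_sir_one(self):
        unit = self.unit(5)
        ref = aggregate_reference([unit])
        result = compute_sir(unit, ref)
        if unit.total_observed() > 0:
            assert result.sir == pytest.approx(1.0)

    def test_mismatched_band_edges_rejected(self):
        cell = ("500-999 g", 0)
        u1 = UnitSirAggregate((1, 8), {cell: 10}, {"all": {}})
        u2 = UnitSirAggregate((1, 9), {cell: 10}, {"all": {}})
        with pytest.raises(ValidationError, match="band edges"):
            aggregate_reference([u1, u2])

    def test_yaml_round_trip(self, tmp_path):
        unit = self.unit(3)
        ref = aggregate_reference([unit])
        path = tmp_path / "reference_rates.yaml"
        ref.to_yaml(path)
        back = ReferenceRates.from_yaml(path)
        assert back.band_edges == ref.band_edges
        for key, cells in ref.rates.items():
            for cell, rate in cells.items():
                assert back.rates[key][cell] == pytest.approx(rate)
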