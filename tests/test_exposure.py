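"""Day-of-life arithmetic and factor-day accounting."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from neosurv.cohort import DailyExposureRecord, Device, Feeding, \
    ValidationError
from neosurv.config import DefinitionsConfig
from neosurv.eligibility import compute_surveillance_window
from neosurv.exposure import (
    compute_device_days,
    compute_patient_days,
    day_of_life,
    summarize_exposures,
)

from conftest import day, make_patient, make_stay


class TestDayOfLife:
    def test_birth_day_is_day_one(self):
        assert day_of_life(dt.date(2025, 1, 1), dt.date(2025, 1, 1)) == 1

    def test_simple_arithmetic(self):
        assert day_of_life(dt.date(2025, 1, 5), dt.date(2025, 1, 1)) == 5

    def test_month_boundary(self):
        # calendar oracle: Feb 27 -> Mar 2 spans 4 days of life
        assert day_of_life(dt.date(2025, 3, 2), dt.date(2025, 2, 27)) == 4

    def test_strictly_increasing(self):
        birth = dt.date(2025, 2, 25)
        values = [day_of_life(birth + dt.timedelta(days=i), birth)
                  for i in range(40)]
        assert values == sorted(set(values))

    def test_before_birth_is_error(self):
        with pytest.raises(ValidationError):
            day_of_life(dt.date(2024, 12, 31), dt.date(2025, 1, 1))


def window_for(los=30, stays=None):
    patient = make_patient(los=los)
    return compute_surveillance_window(
        patient, stays or [make_stay(end=los)])


class TestPatientDays:
    def test_thirty_day_window(self):
        assert compute_patient_days(window_for(30)) == 30

    def test_same_day_admission_and_discharge_counts_one(self):
        # no minimum time on the unit is required for a patient-day
        assert compute_patient_days(window_for(1, [make_stay(end=1)])) == 1

    def test_merged_window_counts_present_days_only(self):
        window = window_for(20, [make_stay(end=10),
                                 make_stay(start=12, end=20)])
        assert compute_patient_days(window) == 19


def exposure(on, **kw):
    return DailyExposureRecord(patient_id="P1", date=day(on), **kw)


class TestDeviceDays:
    def test_twelve_hours_qualifies(self, defs):
        window = window_for(5)
        rows = [exposure(1, cvc_hours=12.0)]
        assert compute_device_days(rows, window, Device.CVC, defs) == 1

    def test_below_twelve_hours_does_not(self, defs):
        window = window_for(5)
        rows = [exposure(1, cvc_hours=11.5)]
        assert compute_device_days(rows, window, Device.CVC, defs) == 0

    def test_random_grids_match_row_scan(self, defs):
        # row-scan oracle over randomized 20-day exposure grids
        rng = np.random.default_rng(3)
        window = window_for(20)
        for _ in range(100):
            rows = [exposure(i + 1,
                             cvc_hours=float(rng.uniform(0, 24)),
                             niv_hours=float(rng.uniform(0, 24)))
                    for i in range(20)]
            for device in (Device.CVC, Device.NIV):
                expected = sum(1 for r in rows
                               if r.device_hours(device) >= 12.0)
                assert compute_device_days(
                    rows, window, device, defs) == expected


class TestFactorDays:
    def test_kangaroo_two_hour_threshold(self, defs):
        window = window_for(5)
        rows = [exposure(1, kangaroo_hours=1.9),
                exposure(2, kangaroo_hours=2.0)]
        assert summarize_exposures(rows, window, defs).kangaroo_days == 1

    def test_antibiotics_counted_cumulatively_and_per_substance(self, defs):
        window = window_for(5)
        rows = [exposure(1, antibiotic_substances=frozenset(
            {"ampicillin", "gentamicin"}))]
        summary = summarize_exposures(rows, window, defs)
        assert summary.antibiotic_days_total == 1
        assert summary.antibiotic_days_by_substance == {
            "ampicillin": 1, "gentamicin": 1}

    def test_mixed_feeding_never_counts_as_breast_milk(self, defs):
        window = window_for(10)
        rows = [exposure(i + 1, enteral_feeding=Feeding.mixed_or_formula)
                for i in range(10)]
        assert summarize_exposures(rows, window, defs).breast_milk_days == 0

    def test_rows_outside_window_ignored_with_warning(self, defs):
        window = window_for(5)
        rows = [exposure(1, probiotic_given=True),
                exposure(9, probiotic_given=True)]
        summary = summarize_exposures(rows, window, defs)
        assert summary.probiotic_days == 1
        assert any("outside" in w for w in summary.warnings)

    def test_every_factor_bounded_by_patient_days(self, defs):
        rng = np.random.default_rng(8)
        window = window_for(15)
        rows = [exposure(i + 1,
                         cvc_hours=float(rng.uniform(0, 24)),
                         kangaroo_hours=float(rng.uniform(0, 6)),
                         probiotic_given=bool(rng.random() < 0.5))
                for i in range(15)]
        s = summarize_exposures(rows, window, defs)
        for count in (*s.device_days.values(), s.antibiotic_days_total,
                      s.breast_milk_days, s.probiotic_days, s.kangaroo_days):
            assert 0 <= count <= s.patient_days
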