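"""Inclusion criteria and surveillance-window merging."""

import datetime as dt
import random

import pytest

from neosurv.cohort import EndReason, StayInterval, ValidationError
from neosurv.eligibility import (
    assess_eligibility,
    compute_surveillance_window,
    gap_hours,
)

from conftest import day, make_patient, make_stay


class TestEligibility:
    def test_vlbw_alone_qualifies(self):
        # 1499 g at 33+0 weeks: weight criterion alone suffices
        included, reason = assess_eligibility(
            make_patient(birth_weight=1499, ga_weeks=33))
        assert included and reason is None

    def test_vpt_alone_qualifies(self):
        included, _ = assess_eligibility(
            make_patient(birth_weight=1800, ga_weeks=31, ga_days=6))
        assert included

    def test_boundary_neither_criterion(self):
        # both thresholds are strict: 1500 g and exactly 32+0 weeks fail
        included, reason = assess_eligibility(
            make_patient(birth_weight=1500, ga_weeks=32, ga_days=0))
        assert not included
        assert reason == "neither_vlbw_nor_vpt"

    @pytest.mark.parametrize("offset,expected", [
        (119, True), (120, True), (121, False)])
    def test_admission_window_120_days(self, offset, expected):
        included, _ = assess_eligibility(
            make_patient(birth_weight=900, admission_offset=offset))
        assert included is expected

    def test_stillbirth_excluded(self):
        included, reason = assess_eligibility(
            make_patient(live_born=False))
        assert not included and reason == "not_live_born"


class TestWindow:
    def test_single_stay_until_death(self):
        patient = make_patient(los=30, end_reason=EndReason.death)
        window = compute_surveillance_window(
            patient, [make_stay(start=1, end=30)])
        assert window.surveillance_days == tuple(day(i) for i in range(1, 31))
        assert window.end_reason is EndReason.death

    def test_48h_absence_is_bridged(self):
        # one full day absent (24 h) merges; the absent day is not counted
        patient = make_patient(los=20)
        window = compute_surveillance_window(
            patient, [make_stay(end=10), make_stay(start=12, end=20)])
        assert window.surveillance_days == tuple(
            day(i) for i in list(range(1, 11)) + list(range(12, 21)))
        assert not window.warnings

    def test_two_full_days_absent_still_merges(self):
        patient = make_patient(los=20)
        window = compute_surveillance_window(
            patient, [make_stay(end=10), make_stay(start=13, end=20)])
        assert day(13) in window.surveillance_days

    def test_three_day_gap_ends_surveillance(self):
        patient = make_patient(los=20)
        window = compute_surveillance_window(
            patient, [make_stay(end=10), make_stay(start=14, end=20)])
        assert window.surveillance_days == tuple(day(i) for i in range(1, 11))
        assert window.end_reason is EndReason.discharge_or_transfer
        assert window.warnings  # re-admission reported, not included

    def test_gap_hours_oracle(self):
        # enumerate: full days strictly between stays x 24 h
        for gap_days in range(5):
            end = day(10)
            start = day(11 + gap_days)
            assert gap_hours(end, start) == 24 * gap_days

    def test_merging_is_order_independent(self):
        patient = make_patient(los=40)
        stays = [make_stay(end=10), make_stay(start=12, end=20),
                 make_stay(start=22, end=40)]
        reference = compute_surveillance_window(patient, stays)
        rng = random.Random(4)
        for _ in range(10):
            shuffled = stays[:]
            rng.shuffle(shuffled)
            assert compute_surveillance_window(
                patient, shuffled).surveillance_days == \
                reference.surveillance_days

    def test_overlapping_stays_rejected(self):
        patient = make_patient(los=30)
        with pytest.raises(ValidationError, match="overlap"):
            compute_surveillance_window(
                patient, [make_stay(end=10), make_stay(start=10, end=20)])

    def test_window_respects_admission_and_end(self):
        patient = make_patient(los=10)
        window = compute_surveillance_window(
            patient, [StayInterval("P1", day(1), None)])
        assert window.first_day == patient.admission_date
        assert window.last_day == patient.end_date

    def test_excluded_patient_has_empty_window(self):
        patient = make_patient(birth_weight=2000, ga_weeks=38)
        window = compute_surveillance_window(patient, [make_stay()])
        assert not window.included
        assert window.surveillance_days == ()
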