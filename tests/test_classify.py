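"""Episode assembly and the infection-classification rules."""

import datetime as dt

import pytest

from neosurv.cohort import (
    BodySystem,
    Cohort,
    Device,
    FindingCategory,
    HaiType,
    SpecimenType,
    SurgeryRecord,
    ValidationError,
    WoundClass,
)
from neosurv.classify import (
    CandidateEpisode,
    ClassifiedHAI,
    assemble_episodes,
    assess_device_association,
    attribute_ssi,
    classify_cohort,
    classify_episode,
    determine_infection_date,
    flag_mdro,
    is_late_onset,
    link_secondary_bsi,
    suppress_repeats,
)
from neosurv.eligibility import build_windows

from conftest import BIRTH, culture, day, finding, make_patient, make_stay


class TestAssembly:
    def test_gaps_of_two_days_form_one_episode(self, defs):
        findings = [finding("CLIN_SEPSIS_SIGN", d) for d in (1, 3, 5)]
        episodes = assemble_episodes(findings, [], defs)
        assert len(episodes) == 1
        assert episodes[0].element_dates() == [day(1), day(3), day(5)]

    def test_gap_beyond_three_days_splits(self, defs):
        findings = [finding("CLIN_SEPSIS_SIGN", d) for d in (1, 6)]
        assert len(assemble_episodes(findings, [], defs)) == 2

    def test_span_limit_splits_long_chains(self, defs):
        # gaps all fine but accumulated span exceeds 10 days
        findings = [finding("CLIN_SEPSIS_SIGN", d)
                    for d in (1, 3, 5, 7, 9, 11, 13)]
        episodes = assemble_episodes(findings, [], defs)
        assert [e.element_dates() for e in episodes] == [
            [day(d) for d in (1, 3, 5, 7, 9, 11)], [day(13)]]

    def test_body_systems_assemble_independently(self, defs):
        findings = [finding("CLIN_SEPSIS_SIGN", 1),
                    finding("PNEU_CLINICAL", 2,
                            system=BodySystem.respiratory)]
        assert len(assemble_episodes(findings, [], defs)) == 2

    def test_cultures_join_episodes(self, defs):
        episodes = assemble_episodes(
            [finding("CLIN_SEPSIS_SIGN", 3)],
            [culture("escherichia_coli", 2)], defs)
        assert len(episodes) == 1
        assert len(episodes[0].micro) == 1


class TestInfectionDate:
    def test_culture_before_symptoms_wins(self):
        episode = CandidateEpisode(
            "P1", BodySystem.bloodstream,
            findings=[finding("CLIN_SEPSIS_SIGN", 10)],
            micro=[culture("escherichia_coli", 9)])
        assert determine_infection_date(episode) == day(9)

    def test_symptoms_before_culture_win(self):
        episode = CandidateEpisode(
            "P1", BodySystem.bloodstream,
            findings=[finding("CLIN_SEPSIS_SIGN", 10)],
            micro=[culture("escherichia_coli", 12)])
        assert determine_infection_date(episode) == day(10)

    def test_symptoms_only(self):
        episode = CandidateEpisode(
            "P1", BodySystem.bloodstream,
            findings=[finding("CLIN_SEPSIS_SIGN", 10)])
        assert determine_infection_date(episode) == day(10)

    def test_no_symptoms_no_primary_site_is_error(self):
        episode = CandidateEpisode(
            "P1", BodySystem.bloodstream,
            findings=[finding("LAB_SEPSIS_MARKER", 5,
                              category=FindingCategory.laboratory)])
        with pytest.raises(ValidationError):
            determine_infection_date(episode)


class TestLateOnset:
    @pytest.mark.parametrize("dol,expected", [(3, False), (4, True)])
    def test_date_only_fallback_boundary(self, dol, expected):
        assert is_late_onset(day(dol), BIRTH) is expected

    def test_hour_arithmetic_with_birth_time(self):
        # 73 h after birth is late onset, 71 h is not
        assert is_late_onset(dt.date(2025, 1, 4), dt.date(2025, 1, 1),
                             birth_time=dt.time(8, 0),
                             onset_time=dt.time(9, 0))
        assert not is_late_onset(dt.date(2025, 1, 4), dt.date(2025, 1, 1),
                                 birth_time=dt.time(8, 0),
                                 onset_time=dt.time(7, 0))


class TestTaxonomy:
    def bsi_episode(self, findings=(), micro=()):
        return CandidateEpisode("P1", BodySystem.bloodstream,
                                findings=list(findings), micro=list(micro))

    def test_recognized_pathogen_culture_suffices(self, defs, catalog):
        episode = self.bsi_episode(micro=[culture("escherichia_coli", 5)])
        assert classify_episode(episode, catalog, defs) is \
            HaiType.lcbsi_pathogen

    def test_lone_commensal_culture_is_not_an_infection(self, defs, catalog):
        episode = self.bsi_episode(
            micro=[culture("staphylococcus_epidermidis", 5)])
        assert classify_episode(episode, catalog, defs) is None

    def test_commensal_with_clinical_and_laboratory_support(self, defs,
                                                            catalog):
        episode = self.bsi_episode(
            findings=[finding("CLIN_SEPSIS_SIGN", 5),
                      finding("LAB_SEPSIS_MARKER", 5,
                              category=FindingCategory.laboratory)],
            micro=[culture("staphylococcus_epidermidis", 5)])
        assert classify_episode(episode, catalog, defs) is \
            HaiType.lcbsi_commensal

    def test_clinical_sepsis_requires_no_detected_organism(self, defs,
                                                           catalog):
        episode = self.bsi_episode(
            findings=[finding("CLIN_SEPSIS_SIGN", 5),
                      finding("LAB_SEPSIS_MARKER", 5,
                              category=FindingCategory.laboratory)])
        assert classify_episode(episode, catalog, defs) is \
            HaiType.clinical_sepsis

    def test_laboratory_evidence_dominates_clinical_sepsis(self, defs,
                                                           catalog):
        episode = self.bsi_episode(
            findings=[finding("CLIN_SEPSIS_SIGN", 5),
                      finding("LAB_SEPSIS_MARKER", 5,
                              category=FindingCategory.laboratory)],
            micro=[culture("escherichia_coli", 5)])
        assert classify_episode(episode, catalog, defs) is \
            HaiType.lcbsi_pathogen

    def test_pneumonia_needs_all_three_categories(self, defs, catalog):
        full = CandidateEpisode("P1", BodySystem.respiratory, findings=[
            finding("PNEU_CLINICAL", 5, system=BodySystem.respiratory),
            finding("PNEU_IMAGING", 5, category=FindingCategory.imaging,
                    system=BodySystem.respiratory),
            finding("PNEU_LAB", 5, category=FindingCategory.laboratory,
                    system=BodySystem.respiratory)])
        assert classify_episode(full, catalog, defs) is HaiType.pneumonia
        partial = CandidateEpisode("P1", BodySystem.respiratory,
                                   findings=full.findings[:2])
        assert classify_episode(partial, catalog, defs) is None

    def test_nec_surgical_evidence_alone_qualifies(self, defs, catalog):
        episode = CandidateEpisode("P1", BodySystem.gastrointestinal,
                                   findings=[finding(
                                       "NEC_SURGICAL", 5,
                                       category=FindingCategory.surgical_evidence,
                                       system=BodySystem.gastrointestinal)])
        assert classify_episode(episode, catalog, defs) is HaiType.nec

    def test_ssi_depth_from_criterion_codes(self, defs, catalog):
        episode = CandidateEpisode("P1", BodySystem.surgical_site, findings=[
            finding("SSI_LOCAL_SIGN", 5, system=BodySystem.surgical_site),
            finding("SSI_DEEP", 5, system=BodySystem.surgical_site)])
        assert classify_episode(episode, catalog, defs) is HaiType.ssi_deep

    def test_unknown_organism_is_error(self, defs, catalog):
        episode = self.bsi_episode(micro=[culture("unknown_bug", 5)])
        with pytest.raises(ValidationError, match="unknown_bug"):
            classify_episode(episode, catalog, defs)


class TestDeviceAssociation:
    def test_run_ending_the_day_before_onset(self, defs):
        days = {Device.CVC: {day(5), day(6), day(7)}}
        assert assess_device_association(
            HaiType.lcbsi_pathogen, day(8), days, defs) is Device.CVC

    def test_two_day_run_is_not_enough(self, defs):
        days = {Device.CVC: {day(5), day(6)}}
        assert assess_device_association(
            HaiType.lcbsi_pathogen, day(7), days, defs) is None

    def test_run_must_end_at_onset_or_day_before(self, defs):
        days = {Device.CVC: {day(3), day(4), day(5)}}
        assert assess_device_association(
            HaiType.lcbsi_pathogen, day(8), days, defs) is None

    def test_cvc_precedes_pvc(self, defs):
        days = {Device.CVC: {day(5), day(6), day(7)},
                Device.PVC: {day(5), day(6), day(7)}}
        assert assess_device_association(
            HaiType.clinical_sepsis, day(7), days, defs) is Device.CVC

    def test_pneumonia_uses_ventilation_devices(self, defs):
        days = {Device.INV: {day(5), day(6), day(7)},
                Device.CVC: {day(5), day(6), day(7)}}
        assert assess_device_association(
            HaiType.pneumonia, day(8), days, defs) is Device.INV


def surgery(sid="S1", on=10, implant=False, pid="P1"):
    return SurgeryRecord(
        surgery_id=sid, patient_id=pid, description="laparotomy",
        date=day(on), duration_minutes=60, main_procedure_code="KDQ.AA",
        asa_score=3, wound_class=WoundClass.clean_contaminated,
        implant=implant)


class TestSsiAttribution:
    @pytest.mark.parametrize("delta,expected", [
        (29, True), (30, True), (31, False)])
    def test_thirty_day_window_boundary(self, defs, delta, expected):
        got = attribute_ssi(HaiType.ssi_superficial, day(10 + delta),
                            [surgery(on=10)], defs)
        assert (got == "S1") is expected

    @pytest.mark.parametrize("delta,expected", [
        (89, True), (90, True), (91, False)])
    def test_ninety_day_implant_window_for_deep_infections(
            self, defs, delta, expected):
        got = attribute_ssi(HaiType.ssi_organ_space, day(10 + delta),
                            [surgery(on=10, implant=True)], defs)
        assert (got == "S1") is expected

    def test_superficial_has_no_implant_extension(self, defs):
        assert attribute_ssi(HaiType.ssi_superficial, day(55),
                             [surgery(on=10, implant=True)], defs) is None

    def test_no_extension_without_implant(self, defs):
        assert attribute_ssi(HaiType.ssi_organ_space, day(90),
                             [surgery(on=10, implant=False)], defs) is None

    def test_most_recent_qualifying_surgery_wins(self, defs):
        surgeries = [surgery("S1", on=5), surgery("S2", on=20)]
        assert attribute_ssi(HaiType.ssi_deep, day(25), surgeries,
                             defs) == "S2"


def hai(on, hai_type=HaiType.lcbsi_pathogen, organisms=(), span=0, pid="P1"):
    episode = CandidateEpisode(
        pid, BodySystem.bloodstream,
        findings=[finding("CLIN_SEPSIS_SIGN", on + k, pid=pid)
                  for k in range(span + 1)])
    return ClassifiedHAI(
        patient_id=pid, hai_type=hai_type, infection_date=day(on),
        day_of_life=on, late_onset=True, organisms=tuple(organisms),
        episode=episode)


class TestRepeatSuppression:
    def test_same_type_within_14_days_merges_organisms(self, defs):
        first = hai(1, organisms=(("escherichia_coli", frozenset()),))
        second = hai(10, organisms=(("klebsiella_pneumoniae", frozenset()),))
        kept = suppress_repeats([first, second], defs)
        assert len(kept) == 1
        assert [o for o, _ in kept[0].organisms] == [
            "escherichia_coli", "klebsiella_pneumoniae"]

    def test_14_days_with_symptom_free_period_counts_twice(self, defs):
        kept = suppress_repeats([hai(1), hai(15)], defs)
        assert len(kept) == 2

    def test_13_days_is_still_suppressed(self, defs):
        assert len(suppress_repeats([hai(1), hai(14)], defs)) == 1

    def test_no_symptom_free_day_suppresses_even_after_14_days(self, defs):
        first, second = hai(1, span=0), hai(15)
        # every intervening day carries a bloodstream symptom
        symptoms = {("P1", BodySystem.bloodstream):
                    {day(d) for d in range(1, 16)}}
        kept = suppress_repeats([first, second], defs, symptoms)
        assert len(kept) == 1

    def test_different_organ_systems_do_not_interact(self, defs):
        resp = ClassifiedHAI("P1", HaiType.pneumonia, day(5), 5, True,
                             episode=CandidateEpisode(
                                 "P1", BodySystem.respiratory,
                                 findings=[finding(
                                     "PNEU_CLINICAL", 5,
                                     system=BodySystem.respiratory)]))
        kept = suppress_repeats([hai(1), resp], defs)
        assert len(kept) == 2


class TestSecondaryBsi:
    def nec(self, on):
        return ClassifiedHAI("P1", HaiType.nec, day(on), on, True,
                             episode=CandidateEpisode(
                                 "P1", BodySystem.gastrointestinal))

    def test_temporal_overlap_without_primary_organisms(self, defs):
        lcbsi = hai(14, organisms=(("escherichia_coli", frozenset()),))
        out = link_secondary_bsi([self.nec(12), lcbsi], defs)
        bsi = [h for h in out if h.patient_id == "P1"
               and h.hai_type is HaiType.secondary_bsi]
        assert len(bsi) == 1
        assert bsi[0].secondary_to == f"nec@{day(12)}"

    def test_organism_mismatch_stays_primary(self, defs):
        pneumonia = ClassifiedHAI(
            "P1", HaiType.pneumonia, day(12), 12, True,
            organisms=(("pseudomonas_aeruginosa", frozenset()),),
            episode=CandidateEpisode("P1", BodySystem.respiratory))
        lcbsi = hai(14, organisms=(("escherichia_coli", frozenset()),))
        out = link_secondary_bsi([pneumonia, lcbsi], defs)
        assert all(h.hai_type is not HaiType.secondary_bsi for h in out)

    def test_outside_active_window_stays_primary(self, defs):
        lcbsi = hai(40, organisms=(("escherichia_coli", frozenset()),))
        out = link_secondary_bsi([self.nec(12), lcbsi], defs)
        assert all(h.hai_type is not HaiType.secondary_bsi for h in out)


class TestMdro:
    def test_any_marker_flags(self):
        is_mdro, markers = flag_mdro((("staphylococcus_aureus",
                                       frozenset({"MRSA"})),))
        assert is_mdro and markers == frozenset({"MRSA"})

    def test_no_marker_no_flag(self):
        is_mdro, markers = flag_mdro((("escherichia_coli", frozenset()),))
        assert not is_mdro and not markers

    def test_markers_aggregate_across_organisms(self):
        is_mdro, markers = flag_mdro((
            ("escherichia_coli", frozenset({"3GCR"})),
            ("klebsiella_pneumoniae", frozenset({"carbapenem_resistant"}))))
        assert is_mdro
        assert markers == frozenset({"3GCR", "carbapenem_resistant"})


class TestPipeline:
    def test_early_onset_episodes_never_counted(self, defs, catalog):
        cohort = Cohort(
            patients=[make_patient()], stays=[make_stay()],
            findings=[finding("CLIN_SEPSIS_SIGN", 2),
                      finding("LAB_SEPSIS_MARKER", 2,
                              category=FindingCategory.laboratory)])
        windows = build_windows(cohort)
        infections, _ = classify_cohort(cohort, windows, defs, catalog)
        assert infections == []

    def test_late_onset_episode_counted_with_device(self, defs, catalog):
        import dataclasses as dc
        from neosurv.cohort import DailyExposureRecord
        exposures = [DailyExposureRecord("P1", day(d), cvc_hours=24.0)
                     for d in (7, 8, 9)]
        cohort = Cohort(
            patients=[make_patient()], stays=[make_stay()],
            exposures=exposures,
            findings=[finding("CLIN_SEPSIS_SIGN", 10),
                      finding("LAB_SEPSIS_MARKER", 10,
                              category=FindingCategory.laboratory)])
        windows = build_windows(cohort)
        infections, _ = classify_cohort(cohort, windows, defs, catalog)
        assert len(infections) == 1
        assert infections[0].hai_type is HaiType.clinical_sepsis
        assert infections[0].device_association is Device.CVC

    def test_shuffled_inputs_give_identical_line_list(self, defs, catalog):
        import random
        from neosurv.simulate import (SimulationConfig, canonical_line_list,
                                      generate_with_truth)
        cohort, _ = generate_with_truth(SimulationConfig(n_patients=30,
                                                         seed=2))
        windows = build_windows(cohort)
        base, _ = classify_cohort(cohort, windows, defs, catalog)
        rng = random.Random(0)
        for _ in range(3):
            rng.shuffle(cohort.findings)
            rng.shuffle(cohort.microbiology)
            rng.shuffle(cohort.exposures)
            again, _ = classify_cohort(cohort, windows, defs, catalog)
            assert canonical_line_list(again) == canonical_line_list(base)
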