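"""Unit and property tests for the GDMT scoring engine."""

import dataclasses

import pytest
from hypothesis import given

from gdmttrial.errors import ConfigError, DataError, UnscreenedError
from gdmttrial.scoring import (
    Basis,
    Component,
    DoseTable,
    DrugClass,
    IronStatus,
    LabPanel,
    PatientSnapshot,
    Prescription,
    Reason,
    VitalsReading,
    delta_gdmt,
    dose_ratio,
    gdmt_score,
    iron_deficiency,
    is_omt,
    score_component,
    time_to_omt,
    valid_reasons,
)

from conftest import TABLE as TABLE_, snapshots


def snap(day=0, prescriptions=(), potassium=4.3, egfr=70.0, vitals=(),
         iron=IronStatus(), allergies=frozenset(), symptomatic=False):
    return PatientSnapshot(
        day=day, prescriptions=tuple(prescriptions),
        labs=LabPanel(potassium=potassium, egfr=egfr, measured_on=day),
        vitals_history=tuple(vitals), iron=iron, allergies=allergies,
        symptomatic_hypotension=symptomatic)


def reading(day, sbp=120.0, hr=75.0):
    return VitalsReading(day=day, systolic_bp=sbp, diastolic_bp=min(sbp - 20, 80),
                         heart_rate=hr, weight=80.0)


FULL_RX = (
    Prescription("sacubitril/valsartan", DrugClass.ARNI, 400.0),
    Prescription("bisoprolol", DrugClass.BETA_BLOCKER, 10.0),
    Prescription("spironolactone", DrugClass.MRA, 50.0),
    Prescription("dapagliflozin", DrugClass.SGLT2I, 10.0),
)
IRON_REPLETE = IronStatus(screened_on=0, ferritin=350.0, tsat=30.0)


class TestDoseRatio:
    @pytest.mark.parametrize("dose,expected", [
        (10.0, 1.0),   # at target
        (0.0, 0.0),    # not taking it
        (5.0, 0.5),    # half target
        (20.0, 1.0),   # above target saturates
    ])
    def test_ratio_of_bisoprolol(self, dose_table, dose, expected):
        p = Prescription("bisoprolol", DrugClass.BETA_BLOCKER, dose)
        assert dose_ratio(p, dose_table) == expected

    def test_unknown_drug_is_a_config_error_naming_it(self, dose_table):
        p = Prescription("novodrug", DrugClass.MRA, 10.0)
        with pytest.raises(ConfigError, match="novodrug"):
            dose_ratio(p, dose_table)


class TestDoseTable:
    def test_every_class_must_be_covered(self):
        with pytest.raises(ConfigError, match="missing"):
            DoseTable((("bisoprolol", DrugClass.BETA_BLOCKER, 10.0),))

    def test_duplicate_names_rejected(self, dose_table):
        entries = dose_table.entries + (("bisoprolol", DrugClass.BETA_BLOCKER, 5.0),)
        with pytest.raises(ConfigError, match="duplicate"):
            DoseTable(entries)

    def test_tsv_round_trip(self, tmp_path, dose_table):
        path = tmp_path / "doses.tsv"
        lines = ["drug_name\tdrug_class\ttarget_daily_dose_mg"]
        lines += [f"{n}\t{c.value}\t{d}" for n, c, d in dose_table.entries]
        path.write_text("\n".join(lines) + "\n")
        assert DoseTable.from_tsv(path).entries == dose_table.entries


class TestValidReasons:
    def test_persistent_hypotension_two_low_readings(self):
        s = snap(day=14, vitals=[reading(5, sbp=88), reading(12, sbp=90)])
        got = {r.reason for r in valid_reasons(s)}
        assert Reason.PERSISTENT_SBP_LE_90 in got
        (r,) = [r for r in valid_reasons(s) if r.reason is Reason.PERSISTENT_SBP_LE_90]
        assert r.applies_to == frozenset(DrugClass)  # all four medication groups

    def test_single_low_reading_is_not_persistent(self):
        s = snap(day=14, vitals=[reading(5, sbp=88), reading(12, sbp=91)])
        assert Reason.PERSISTENT_SBP_LE_90 not in {r.reason for r in valid_reasons(s)}

    def test_low_readings_outside_lookback_ignored(self):
        s = snap(day=40, vitals=[reading(2, sbp=85), reading(3, sbp=85),
                                 reading(38, sbp=120)])
        assert Reason.PERSISTENT_SBP_LE_90 not in {r.reason for r in valid_reasons(s)}

    def test_symptomatic_patients_use_the_symptomatic_reason(self):
        s = snap(day=14, vitals=[reading(5, sbp=88), reading(12, sbp=89)],
                 symptomatic=True)
        got = {r.reason for r in valid_reasons(s)}
        assert Reason.SYMPTOMATIC_HYPOTENSION in got
        assert Reason.PERSISTENT_SBP_LE_90 not in got

    @pytest.mark.parametrize("potassium,fires", [(5.0, False), (5.01, True)])
    def test_potassium_threshold_is_strict(self, potassium, fires):
        got = {r.reason for r in valid_reasons(snap(potassium=potassium))}
        assert (Reason.K_GT_5 in got) is fires

    @pytest.mark.parametrize("egfr,expect", [
        (30.0, set()),
        (29.9, {Reason.EGFR_LT_30}),
        (25.0, {Reason.EGFR_LT_30}),
        (19.9, {Reason.EGFR_LT_30, Reason.EGFR_LT_20}),
    ])
    def test_egfr_thresholds(self, egfr, expect):
        got = {r.reason for r in valid_reasons(snap(egfr=egfr))
               if r.reason in (Reason.EGFR_LT_30, Reason.EGFR_LT_20)}
        assert got == expect

    def test_egfr_below_30_spares_sglt2i(self):
        reasons = valid_reasons(snap(egfr=25.0))
        (r,) = [x for x in reasons if x.reason is Reason.EGFR_LT_30]
        assert r.applies_to == frozenset(
            {DrugClass.ACE, DrugClass.ARB, DrugClass.ARNI, DrugClass.MRA})
        assert not r.excuses(Component.SGLT2I)

    @pytest.mark.parametrize("hr,fires", [(60.0, True), (61.0, False)])
    def test_bradycardia_threshold_includes_sixty(self, hr, fires):
        s = snap(day=7, vitals=[reading(7, hr=hr)])
        assert (Reason.HR_LE_60 in {r.reason for r in valid_reasons(s)}) is fires

    def test_empty_history_gives_no_bp_or_hr_reasons(self):
        got = {r.reason for r in valid_reasons(snap(vitals=[]))}
        assert not got & {Reason.PERSISTENT_SBP_LE_90, Reason.HR_LE_60}


class TestIronDeficiency:
    # exhaustive truth table over the four decision regions
    @pytest.mark.parametrize("ferritin,tsat,expected", [
        (93.0, 18.0, True),    # ferritin < 100 alone suffices
        (93.0, 25.0, True),
        (150.0, 15.0, True),   # 100 <= ferritin < 300 needs TSAT < 20
        (150.0, 25.0, False),
        (350.0, 15.0, False),  # ferritin >= 300 never deficient
        (350.0, 25.0, False),
        (99.99, 19.99, True),  # boundary: strict comparisons
        (100.0, 20.0, False),
        (299.9, 19.9, True),
        (300.0, 19.9, False),
    ])
    def test_truth_table(self, ferritin, tsat, expected):
        assert iron_deficiency(ferritin, tsat) is expected

    def test_missing_values_are_unscreened_not_false(self):
        with pytest.raises(UnscreenedError):
            iron_deficiency(None, 25.0)
        with pytest.raises(UnscreenedError):
            iron_deficiency(150.0, None)

    def test_low_ferritin_decides_without_tsat(self):
        assert iron_deficiency(93.0, None) is True
        assert iron_deficiency(350.0, None) is False


class TestComponents:
    def test_arni_at_target_scores_both_rasi_and_switch(self, dose_table):
        s = snap(prescriptions=[FULL_RX[0]])
        assert score_component(s, Component.RASI_DOSE, dose_table).value == 1.0
        assert score_component(s, Component.ARNI_SWITCH, dose_table).value == 1.0

    def test_hyperkalemia_excuses_missing_mra(self, dose_table):
        s = snap(potassium=5.4)
        c = score_component(s, Component.MRA_DOSE, dose_table)
        assert c.value == 1.0 and c.basis is Basis.VALID_REASON

    def test_hyperkalemia_does_not_excuse_beta_blocker(self, dose_table):
        s = snap(potassium=5.4)
        c = score_component(s, Component.BB_DOSE, dose_table)
        assert c.value == 0.0

    def test_stale_iron_screening_scores_zero(self, dose_table):
        s = snap(day=400, iron=IronStatus(screened_on=0, ferritin=350.0, tsat=30.0))
        assert score_component(s, Component.IRON, dose_table).value == 0.0

    def test_recent_screening_replete_scores_one(self, dose_table):
        s = snap(day=100, iron=IronStatus(screened_on=0, ferritin=350.0, tsat=30.0))
        assert score_component(s, Component.IRON, dose_table).value == 1.0

    def test_deficient_without_iv_iron_scores_zero(self, dose_table):
        s = snap(iron=IronStatus(screened_on=0, ferritin=50.0, tsat=10.0))
        assert score_component(s, Component.IRON, dose_table).value == 0.0

    def test_deficient_with_iv_iron_scores_one(self, dose_table):
        s = snap(iron=IronStatus(screened_on=0, ferritin=50.0, tsat=10.0,
                                 iv_iron_given=True))
        assert score_component(s, Component.IRON, dose_table).value == 1.0

    def test_allergy_excuses_only_its_class(self, dose_table):
        s = snap(allergies={DrugClass.SGLT2I})
        assert score_component(s, Component.SGLT2I, dose_table).basis is Basis.VALID_REASON
        assert score_component(s, Component.BB_DOSE, dose_table).value == 0.0


class TestTotalScore:
    def test_fully_treated_snapshot_scores_six(self, dose_table):
        s = snap(prescriptions=FULL_RX, iron=IRON_REPLETE)
        assert gdmt_score(s, dose_table).total == 6.0

    def test_untreated_unscreened_snapshot_scores_zero(self, dose_table):
        assert gdmt_score(snap(), dose_table).total == 0.0

    def test_half_dose_beta_blocker_alone_scores_half(self, dose_table):
        s = snap(prescriptions=[
            Prescription("bisoprolol", DrugClass.BETA_BLOCKER, 5.0)])
        assert gdmt_score(s, dose_table).total == 0.5

    def test_delta_is_followup_minus_baseline(self, dose_table):
        base = gdmt_score(snap(), dose_table)
        up = gdmt_score(snap(prescriptions=FULL_RX, iron=IRON_REPLETE), dose_table)
        assert delta_gdmt(base, up) == 6.0
        assert delta_gdmt(up, up) == 0.0
        assert delta_gdmt(up, base) == -6.0

    def test_ace_and_arni_together_rejected(self, dose_table):
        with pytest.raises(DataError, match="medication group"):
            snap(prescriptions=[
                FULL_RX[0], Prescription("ramipril", DrugClass.ACE, 10.0)])


class TestOMT:
    def test_omt_iff_all_components_one(self, dose_table):
        full = gdmt_score(snap(prescriptions=FULL_RX, iron=IRON_REPLETE), dose_table)
        assert is_omt(full)
        no_iron = gdmt_score(snap(prescriptions=FULL_RX), dose_table)
        assert not is_omt(no_iron)
        assert is_omt(no_iron, components=[c for c in Component
                                           if c is not Component.IRON])

    def test_ace_at_target_is_not_omt_without_switch(self, dose_table):
        s = snap(prescriptions=(
            Prescription("ramipril", DrugClass.ACE, 10.0),) + FULL_RX[1:],
            iron=IRON_REPLETE)
        score = gdmt_score(s, dose_table)
        assert score.total == 5.0 and not is_omt(score)

    def test_time_to_omt_first_qualifying_day(self, dose_table):
        t = [snap(day=0), snap(day=30, prescriptions=FULL_RX, iron=IRON_REPLETE),
             snap(day=60, prescriptions=FULL_RX, iron=IRON_REPLETE)]
        # iron screened on day 0 stays within the window
        assert time_to_omt(t, dose_table) == (30, True)

    def test_never_reached_is_censored_at_horizon(self, dose_table):
        assert time_to_omt([snap(day=0), snap(day=84)], dose_table) == (84, False)

    def test_omt_at_baseline(self, dose_table):
        t = [snap(day=0, prescriptions=FULL_RX, iron=IRON_REPLETE)]
        assert time_to_omt(t, dose_table) == (0, True)

    def test_empty_trajectory_is_an_error(self, dose_table):
        with pytest.raises(DataError):
            time_to_omt([], dose_table)


class TestScoreProperties:
    @given(s=snapshots())
    def test_bounds_and_total_is_component_sum(self, s):
        score = gdmt_score(s, TABLE_)
        assert all(0.0 <= c.value <= 1.0 for c in score.components)
        assert score.total == sum(c.value for c in score.components)
        assert 0.0 <= score.total <= 6.0

    @given(s=snapshots())
    def test_omt_equivalent_to_total_six(self, s):
        score = gdmt_score(s, TABLE_)
        assert is_omt(score) == (score.total == 6.0)

    @given(s=snapshots())
    def test_increasing_any_dose_never_lowers_the_score(self, s):
        before = gdmt_score(s, TABLE_).total
        for i, p in enumerate(s.prescriptions):
            bumped = list(s.prescriptions)
            bumped[i] = dataclasses.replace(p, daily_dose=p.daily_dose * 2 + 1)
            s2 = dataclasses.replace(s, prescriptions=tuple(bumped))
            assert gdmt_score(s2, TABLE_).total >= before

    @given(s=snapshots())
    def test_adding_an_allergy_never_lowers_any_component(self, s):
        before = gdmt_score(s, TABLE_)
        for cls in DrugClass:
            s2 = dataclasses.replace(s, allergies=s.allergies | {cls})
            after = gdmt_score(s2, TABLE_)
            for c in Component:
                assert after[c].value >= before[c].value
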