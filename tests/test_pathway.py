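"""Pathway assignment and the titration decision engine."""

import datetime as dt
import random

import pytest

from htn_rms import (
    Action,
    DrugClass,
    GoalStatus,
    GoalStatusKind,
    MedicationState,
    Pathway,
    PathwayKind,
    SecondaryScreenPanel,
    apply_covid_mode,
    assign_pathway,
    consolidate_combo,
    goal_status,
    next_action,
    select_raas_agent,
    weekly_average,
)

AS_OF = dt.date(2022, 6, 6)
WEEK_START = AS_OF - dt.timedelta(days=7)


def above_goal(helpers, thresholds, sbp=150, dbp=95, hr=70):
    summary = weekly_average(helpers.make_week(sbp, dbp, start=WEEK_START, hr=hr),
                             WEEK_START, thresholds)
    return summary, goal_status(summary, False, thresholds)


def standard():
    return Pathway(kind=PathwayKind.STANDARD)


class TestAssignPathway:
    def test_clean_male_goes_standard(self, helpers):
        p = helpers.make_profile(sex="male")
        labs = helpers.make_labs(egfr=75, uacr=10)
        assert assign_pathway(p, labs).kind is PathwayKind.STANDARD

    def test_low_egfr_goes_raas_first(self, helpers):
        p = helpers.make_profile(sex="female", age=60)
        labs = helpers.make_labs(egfr=50)
        assert assign_pathway(p, labs).kind is PathwayKind.RAAS_FIRST

    def test_childbearing_outranks_raas_indications(self, helpers):
        p = helpers.make_profile(sex="female", age=40, diabetes=True,
                                 contraception=False)
        labs = helpers.make_labs(egfr=50)
        assert assign_pathway(p, labs).kind is PathwayKind.CHILDBEARING

    def test_contraception_returns_to_standard_rules(self, helpers):
        p = helpers.make_profile(sex="female", age=40, contraception=True)
        labs = helpers.make_labs(egfr=75, uacr=5)
        assert assign_pathway(p, labs).kind is PathwayKind.STANDARD

    @pytest.mark.parametrize("kwargs,labs_kwargs,expected", [
        ({"diabetes": True}, {}, PathwayKind.RAAS_FIRST),
        ({}, {"uacr": 45}, PathwayKind.RAAS_FIRST),
        ({}, {"uacr": None}, PathwayKind.STANDARD),  # missing uacr treated < 30
    ])
    def test_raas_indications(self, helpers, kwargs, labs_kwargs, expected):
        p = helpers.make_profile(sex="male", **kwargs)
        labs = helpers.make_labs(**{"egfr": 80, "uacr": 10, **labs_kwargs})
        assert assign_pathway(p, labs).kind is expected


class TestSelectRaasAgent:
    def test_naive_gets_program_default_arb(self, helpers, dosing_table):
        agent, action = select_raas_agent([], dosing_table)
        assert (agent, action) == ("irbesartan", Action.START)

    def test_losartan_switched_to_potent_arb(self, helpers, dosing_table):
        regimen = [helpers.med("losartan", 1, as_of=AS_OF)]
        agent, action = select_raas_agent(regimen, dosing_table)
        assert (agent, action) == ("irbesartan", Action.SWITCH)

    def test_lisinopril_titrated_in_place(self, helpers, dosing_table):
        regimen = [helpers.med("lisinopril", 0, as_of=AS_OF)]
        agent, action = select_raas_agent(regimen, dosing_table)
        assert (agent, action) == ("lisinopril", Action.TITRATE)

    def test_double_raas_blockade_rejected(self, helpers, dosing_table):
        regimen = [helpers.med("lisinopril", 0, as_of=AS_OF),
                   helpers.med("irbesartan", 0, as_of=AS_OF)]
        with pytest.raises(ValueError):
            select_raas_agent(regimen, dosing_table)


class TestNextAction:
    def test_at_goal_holds_for_maintenance(self, helpers, thresholds, dosing_table):
        summary, _ = above_goal(helpers, thresholds, sbp=120, dbp=70)
        goal = goal_status(summary, False, thresholds)
        rec = next_action(helpers.make_profile(), standard(), [], goal, summary,
                          helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.HOLD
        assert "AT_GOAL" in rec.rationale_codes

    def test_naive_standard_patient_starts_ccb(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        rec = next_action(helpers.make_profile(), standard(), [], goal, summary,
                          helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.START
        assert rec.agent == "amlodipine"

    def test_ccb_below_max_is_titrated_before_adding(self, helpers, thresholds,
                                                     dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent, rec.target_dose_step) == (Action.TITRATE,
                                                                 "amlodipine", 2)

    def test_ccb_at_max_adds_arb(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent) == (Action.ADD, "irbesartan")
        assert rec.requires_lab_gate

    def test_ccb_intolerance_moves_to_arb(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 0, as_of=AS_OF, intolerant=True)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent) == (Action.ADD, "irbesartan")

    def test_lab_gate_block_converts_to_hold(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(k=5.4),
                          as_of=AS_OF, thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.HOLD
        assert "LAB_GATE_BLOCKED" in rec.rationale_codes
        assert "K_GE_5_2" in rec.rationale_codes

    def test_titration_lockout_holds(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 1, weeks_ago=0.5, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.HOLD
        assert "TITRATION_LOCKOUT" in rec.rationale_codes

    def test_mra_lockout_is_six_weeks(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        maxed = [helpers.med("amlodipine", 2, weeks_ago=20, as_of=AS_OF),
                 helpers.med("irbesartan", 2, weeks_ago=16, as_of=AS_OF),
                 helpers.med("hydrochlorothiazide", 1, weeks_ago=12, as_of=AS_OF)]
        actions = {}
        for weeks in range(1, 11):
            regimen = maxed + [helpers.med("spironolactone", 0, weeks_ago=weeks,
                                           as_of=AS_OF)]
            rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                              regimen, goal, summary, helpers.make_labs(),
                              as_of=AS_OF, thresholds=thresholds,
                              dosing_table=dosing_table)
            actions[weeks] = rec.action
        assert all(actions[w] is Action.HOLD for w in range(1, 6))
        assert actions[6] is Action.TITRATE

    def test_medication_naive_stage1_low_risk_gets_lifestyle_trial(
            self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=134, dbp=84)
        p = helpers.make_profile(ascvd_risk_10yr=0.05)
        rec = next_action(p, standard(), [], goal, summary, helpers.make_labs(),
                          as_of=AS_OF, thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.LIFESTYLE_TRIAL

    def test_stage2_bp_skips_lifestyle_trial(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=145, dbp=84)
        p = helpers.make_profile(ascvd_risk_10yr=0.05)
        rec = next_action(p, standard(), [], goal, summary, helpers.make_labs(),
                          as_of=AS_OF, thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.START

    def test_max_hctz_near_goal_switches_to_chlorthalidone(self, helpers, thresholds,
                                                           dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=135, dbp=70)
        assert goal.near_goal_within_margin
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("irbesartan", 2, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent) == (Action.SWITCH, "chlorthalidone")

    def test_max_three_drugs_far_from_goal_orders_secondary_screen(
            self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=155, dbp=95)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("irbesartan", 2, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.ORDER_SECONDARY_LABS

    def test_positive_secondary_screen_refers(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=155, dbp=95)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("irbesartan", 2, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                          secondary_screen=SecondaryScreenPanel(reviewed_positive=True),
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.REFER_SPECIALIST

    def test_negative_screen_adds_mra_when_potassium_permits(
            self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=155, dbp=95)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("irbesartan", 2, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 1, as_of=AS_OF)]
        screen = SecondaryScreenPanel(reviewed_positive=False)
        rec = next_action(helpers.make_profile(sex="male", medication_naive=False),
                          standard(), regimen, goal, summary,
                          helpers.make_labs(k=4.0), as_of=AS_OF,
                          secondary_screen=screen,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent) == (Action.ADD, "eplerenone")
        rec_f = next_action(helpers.make_profile(sex="female", age=60,
                                                 medication_naive=False),
                            standard(), regimen, goal, summary,
                            helpers.make_labs(k=4.0), as_of=AS_OF,
                            secondary_screen=screen,
                            thresholds=thresholds, dosing_table=dosing_table)
        assert rec_f.agent == "spironolactone"

    def test_high_k_diverts_fourth_line_to_bb(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=155, dbp=95)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("irbesartan", 2, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          regimen, goal, summary, helpers.make_labs(k=5.5),
                          as_of=AS_OF,
                          secondary_screen=SecondaryScreenPanel(reviewed_positive=False),
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent) == (Action.ADD, "labetalol")

    def test_reactive_airway_prefers_metoprolol(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=155, dbp=95)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("irbesartan", 2, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False,
                                               reactive_airway=True),
                          standard(), regimen, goal, summary,
                          helpers.make_labs(k=5.5), as_of=AS_OF,
                          secondary_screen=SecondaryScreenPanel(reviewed_positive=False),
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.agent == "metoprolol"

    def test_bb_titration_blocked_below_hr_55(self, helpers, thresholds, dosing_table):
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("labetalol", 0, as_of=AS_OF)]
        pathway = Pathway(kind=PathwayKind.CHILDBEARING)
        p = helpers.make_profile(sex="female", age=40, medication_naive=False)
        emitted = {}
        for hr in (50, 54, 55, 60):
            summary, goal = above_goal(helpers, thresholds, hr=hr)
            rec = next_action(p, pathway, regimen, goal, summary,
                              helpers.make_labs(), as_of=AS_OF,
                              thresholds=thresholds, dosing_table=dosing_table)
            emitted[hr] = rec.action
        assert emitted[50] is Action.PHYSICIAN_CONVERSATION
        assert emitted[54] is Action.PHYSICIAN_CONVERSATION
        assert emitted[55] is Action.TITRATE
        assert emitted[60] is Action.TITRATE

    def test_safety_floor_triggers_physician_conversation(self, helpers, thresholds,
                                                          dosing_table):
        summary, _ = above_goal(helpers, thresholds, sbp=135, dbp=48)
        goal = goal_status(summary, False, thresholds)
        assert goal.safety_floor_flag
        rec = next_action(helpers.make_profile(medication_naive=False), standard(),
                          [helpers.med("amlodipine", 1, as_of=AS_OF)], goal, summary,
                          helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.PHYSICIAN_CONVERSATION

    def test_childbearing_pathway_exhaustion_refers(self, helpers, thresholds,
                                                    dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF),
                   helpers.med("labetalol", 2, as_of=AS_OF)]
        p = helpers.make_profile(sex="female", age=40, medication_naive=False)
        rec = next_action(p, Pathway(kind=PathwayKind.CHILDBEARING), regimen, goal,
                          summary, helpers.make_labs(), as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.REFER_SPECIALIST

    def test_two_raas_blockers_rejected(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("irbesartan", 0, as_of=AS_OF),
                   helpers.med("lisinopril", 0, as_of=AS_OF)]
        with pytest.raises(ValueError):
            next_action(helpers.make_profile(), standard(), regimen, goal, summary,
                        helpers.make_labs(), as_of=AS_OF,
                        thresholds=thresholds, dosing_table=dosing_table)

    def test_determinism(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds)
        regimen = [helpers.med("amlodipine", 1, as_of=AS_OF)]
        recs = {
            next_action(helpers.make_profile(medication_naive=False), standard(),
                        regimen, goal, summary, helpers.make_labs(), as_of=AS_OF,
                        thresholds=thresholds,
                        dosing_table=dosing_table).model_dump_json()
            for _ in range(5)
        }
        assert len(recs) == 1


class TestCovidMode:
    def _covid(self, labs_available):
        return Pathway(kind=PathwayKind.STANDARD, covid_mode=True,
                       labs_available=labs_available)

    def test_no_labs_severe_substitutes_lab_free_class(self, helpers, thresholds,
                                                       dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=145, dbp=88)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF)]  # next would be ARB
        rec = next_action(helpers.make_profile(medication_naive=False),
                          self._covid(labs_available=False), regimen, goal, summary,
                          None, as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.agent == "labetalol"  # CCB maxed, so the BB is next
        assert rec.action is Action.ADD

    def test_no_labs_mild_defers_to_lifestyle(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=135, dbp=85)
        regimen = [helpers.med("amlodipine", 2, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False),
                          self._covid(labs_available=False), regimen, goal, summary,
                          None, as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert rec.action is Action.LIFESTYLE_TRIAL

    def test_lab_free_next_step_unchanged(self, helpers, thresholds, dosing_table):
        summary, goal = above_goal(helpers, thresholds, sbp=150, dbp=95)
        regimen = [helpers.med("amlodipine", 1, as_of=AS_OF)]
        rec = next_action(helpers.make_profile(medication_naive=False),
                          self._covid(labs_available=False), regimen, goal, summary,
                          None, as_of=AS_OF,
                          thresholds=thresholds, dosing_table=dosing_table)
        assert (rec.action, rec.agent, rec.target_dose_step) == (Action.TITRATE,
                                                                 "amlodipine", 2)

    def test_labs_available_uses_conservative_start(self, helpers, thresholds,
                                                    dosing_table):
        from htn_rms import Recommendation
        base = Recommendation(action=Action.ADD, agent="irbesartan",
                              target_dose_step=1)
        summary, goal = above_goal(helpers, thresholds)
        out = apply_covid_mode(base, True, goal, summary, [],
                               thresholds, dosing_table)
        assert out.target_dose_step == dosing_table.agent(
            "irbesartan").conservative_start_step
        assert "COVID_CONSERVATIVE_DOSE" in out.rationale_codes

    def test_every_emitted_start_in_no_labs_mode_is_lab_free(self, helpers,
                                                             thresholds, dosing_table):
        """Fuzz: with labs unreachable the engine never starts a gated class."""
        rng = random.Random(11)
        agents = ["amlodipine", "irbesartan", "hydrochlorothiazide", "labetalol"]
        for _ in range(300):
            regimen = []
            for agent in rng.sample(agents, rng.randint(0, 3)):
                entry = dosing_table.agent(agent)
                regimen.append(helpers.med(agent, rng.randint(0, entry.max_step),
                                           weeks_ago=rng.randint(2, 20), as_of=AS_OF))
            sbp = rng.randint(131, 180)
            summary, goal = above_goal(helpers, thresholds, sbp=sbp,
                                       dbp=rng.randint(60, 85))
            try:
                rec = next_action(helpers.make_profile(medication_naive=False),
                                  self._covid(labs_available=False), regimen, goal,
                                  summary, None, as_of=AS_OF,
                                  thresholds=thresholds, dosing_table=dosing_table)
            except ValueError:
                continue
            if rec.action in (Action.START, Action.ADD, Action.TITRATE, Action.SWITCH):
                cls = dosing_table.agent(rec.agent).drug_class
                assert cls in (DrugClass.CCB, DrugClass.BB), rec


class TestConsolidateCombo:
    def test_stable_arb_and_td_consolidate(self, helpers, thresholds, dosing_table):
        regimen = [helpers.med("irbesartan", 2, weeks_ago=8, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 0, weeks_ago=6, as_of=AS_OF)]
        rec = consolidate_combo(regimen, AS_OF, thresholds, dosing_table)
        assert rec is not None
        assert rec.action is Action.CONSOLIDATE_COMBO
        assert rec.agent == "irbesartan/HCTZ"

    def test_td_alone_nothing_to_combine(self, helpers, thresholds, dosing_table):
        regimen = [helpers.med("hydrochlorothiazide", 0, weeks_ago=8, as_of=AS_OF)]
        assert consolidate_combo(regimen, AS_OF, thresholds, dosing_table) is None

    def test_mid_titration_regimen_not_consolidated(self, helpers, thresholds,
                                                    dosing_table):
        regimen = [helpers.med("irbesartan", 1, weeks_ago=1, as_of=AS_OF),
                   helpers.med("hydrochlorothiazide", 0, weeks_ago=6, as_of=AS_OF)]
        assert consolidate_combo(regimen, AS_OF, thresholds, dosing_table) is None


class TestEngineSafetyFuzz:
    def test_dose_step_never_above_max_and_lockout_respected(self, helpers,
                                                             thresholds, dosing_table):
        """Randomised regimens: emitted steps stay on the ladder, lockouts
        hold, maximize-before-add, and never two RAAS blockers."""
        rng = random.Random(2024)
        agents = ["amlodipine", "irbesartan", "lisinopril", "hydrochlorothiazide",
                  "spironolactone", "labetalol"]
        n_dosing = 0
        for _ in range(1500):
            chosen = rng.sample(agents, rng.randint(0, 4))
            if "irbesartan" in chosen and "lisinopril" in chosen:
                chosen.remove("lisinopril")
            regimen = []
            for agent in chosen:
                entry = dosing_table.agent(agent)
                regimen.append(helpers.med(
                    agent, rng.randint(0, entry.max_step),
                    weeks_ago=rng.choice([0.3, 1, 2, 5, 7, 10]), as_of=AS_OF,
                    intolerant=rng.random() < 0.15,
                ))
            summary, goal = above_goal(
                helpers, thresholds, sbp=rng.randint(110, 190),
                dbp=rng.randint(55, 100), hr=rng.randint(45, 90),
            )
            labs = helpers.make_labs(
                k=round(rng.uniform(3.0, 5.8), 1), na=rng.randint(130, 145),
                egfr=rng.randint(25, 100),
            )
            profile = helpers.make_profile(medication_naive=not regimen)
            rec = next_action(profile, standard(), regimen, goal, summary, labs,
                              as_of=AS_OF, thresholds=thresholds,
                              dosing_table=dosing_table)

            if rec.action in (Action.START, Action.ADD, Action.TITRATE, Action.SWITCH):
                n_dosing += 1
                entry = dosing_table.agent(rec.agent)
                assert 0 <= rec.target_dose_step <= entry.max_step
                # lockout: no dosing action while the last change is fresh
                last = max(regimen, key=lambda m: m.last_change_date, default=None)
                if last is not None:
                    weeks = (AS_OF - last.last_change_date).days / 7
                    lockout = (thresholds.titration_lockout_weeks_mra
                               if dosing_table.agent(last.agent).drug_class
                               is DrugClass.MRA
                               else thresholds.titration_lockout_weeks)
                    assert weeks >= lockout, rec
                # maximize-before-add: never ADD while top line titratable
                if rec.action is Action.ADD:
                    new_cls = entry.drug_class
                    for m in regimen:
                        m_cls = dosing_table.agent(m.agent).drug_class
                        if m_cls is new_cls or (m_cls.is_raas and new_cls.is_raas):
                            assert m.intolerant or m.at_max(dosing_table), rec
                # one RAAS slot
                if entry.drug_class.is_raas and rec.action is Action.ADD:
                    assert not any(
                        dosing_table.agent(m.agent).drug_class.is_raas
                        for m in regimen
                    )
        assert n_dosing > 100  # the fuzz actually exercised dosing paths
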