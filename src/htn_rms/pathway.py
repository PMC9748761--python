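"""Pathway assignment and the medication-titration decision engine.

Three first-line pathways: the standard pathway starts a dihydropyridine
CCB; the RAAS-blockade pathway (diabetes, eGFR < 60, or urine
microalbumin/Cr >= 30) starts an ARB/ACEI; women of childbearing
potential (< 45, no contraception) go CCB then labetalol. Escalation is
maximize-before-add through CCB/RAAS/thiazide lines, then a secondary-
cause screen, then MRA or beta blocker as fourth line, then specialist
referral. A COVID risk-mitigation mode prefers lab-free classes (CCB,
then labetalol) when labs are unreachable and conservative dosing when
they are constrained.

The engine is a pure function: one invocation yields exactly one
:class:`Recommendation`, decided in a fixed priority order (at goal,
safety floors, titration lockout, lifestyle trial, titrate, add/switch,
secondary screen, fourth line, refer).
"""

from __future__ import annotations

import datetime as dt
import logging
from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .bp_monitoring import GoalStatus, WeeklyBPSummary
from .core import (
    LAB_REQUIRING_CLASSES,
    RAAS_CLASSES,
    DosingTable,
    DrugClass,
    LabPanel,
    MedicationState,
    PatientProfile,
    Sex,
    Thresholds,
    default_config,
)
from .lab_gates import GateDecision, check_gate

logger = logging.getLogger(__name__)


class PathwayKind(str, Enum):
    STANDARD = "STANDARD"
    RAAS_FIRST = "RAAS_FIRST"
    CHILDBEARING = "CHILDBEARING"


class Pathway(BaseModel):
    kind: PathwayKind
    covid_mode: bool = False
    labs_available: bool = True


class Action(str, Enum):
    START = "START"
    TITRATE = "TITRATE"
    SWITCH = "SWITCH"
    ADD = "ADD"
    HOLD = "HOLD"
    ORDER_SECONDARY_LABS = "ORDER_SECONDARY_LABS"
    REFER_SPECIALIST = "REFER_SPECIALIST"
    LIFESTYLE_TRIAL = "LIFESTYLE_TRIAL"
    CONSOLIDATE_COMBO = "CONSOLIDATE_COMBO"
    PHYSICIAN_CONVERSATION = "PHYSICIAN_CONVERSATION"


#: Actions that place a named agent at a named dose step.
DOSING_ACTIONS = frozenset({Action.START, Action.TITRATE, Action.SWITCH, Action.ADD})


class Recommendation(BaseModel):
    action: Action
    agent: Optional[str] = None
    target_dose_step: Optional[int] = None
    rationale_codes: list[str] = []
    requires_lab_gate: bool = False

    @model_validator(mode="after")
    def _dosing_fields(self) -> "Recommendation":
        if self.action in DOSING_ACTIONS:
            if self.agent is None or self.target_dose_step is None:
                raise ValueError(f"{self.action.value} must carry agent and dose step")
        elif self.action in (Action.HOLD, Action.REFER_SPECIALIST,
                             Action.PHYSICIAN_CONVERSATION, Action.ORDER_SECONDARY_LABS,
                             Action.LIFESTYLE_TRIAL):
            if self.target_dose_step is not None:
                raise ValueError(f"{self.action.value} must not carry a dose step")
        return self


class SecondaryScreenPanel(BaseModel):
    """Secondary-cause screen: renin, aldosterone, potassium, metanephrines.

    Whether the screen is positive is a clinician-lead judgement supplied
    as a boolean, not derived from the analyte values.
    """

    plasma_renin_activity: Optional[float] = None
    aldosterone_concentration: Optional[float] = None
    serum_potassium: Optional[float] = None
    plasma_free_metanephrines: Optional[float] = None
    reviewed_positive: bool = False


# ---------------------------------------------------------------------------
# Pathway assignment
# ---------------------------------------------------------------------------

def assign_pathway(
    profile: PatientProfile,
    labs: Optional[LabPanel],
    covid_mode: bool = False,
    labs_available: bool = True,
    thresholds: Optional[Thresholds] = None,
) -> Pathway:
    """First-line pathway for a patient.

    Childbearing potential (female, < 45, no contraception) outranks the
    RAAS-first indications; a missing urine albumin/Cr is treated as
    below the 30 mg/g cut-off with a logged caveat.
    """
    t = thresholds or default_config()[0]
    if (
        profile.sex is Sex.female
        and profile.age < t.age_childbearing
        and not profile.contraception
    ):
        return Pathway(kind=PathwayKind.CHILDBEARING,
                       covid_mode=covid_mode, labs_available=labs_available)
    uacr = None if labs is None else labs.uacr
    if uacr is None:
        logger.info("uacr missing; treating as < %g mg/g Cr", t.uacr_pathway)
    raas_first = profile.diabetes or (
        labs is not None
        and (labs.egfr < t.egfr_raas_pathway
             or (uacr is not None and uacr >= t.uacr_pathway))
    )
    kind = PathwayKind.RAAS_FIRST if raas_first else PathwayKind.STANDARD
    return Pathway(kind=kind, covid_mode=covid_mode, labs_available=labs_available)


# ---------------------------------------------------------------------------
# Regimen helpers
# ---------------------------------------------------------------------------

def _meds_of_class(regimen: list[MedicationState], cls: DrugClass,
                   table: DosingTable) -> list[MedicationState]:
    return [m for m in regimen if table.agent(m.agent).drug_class is cls]


def _raas_meds(regimen: list[MedicationState], table: DosingTable) -> list[MedicationState]:
    return [m for m in regimen if table.agent(m.agent).drug_class in RAAS_CLASSES]


def _line_exhausted(meds: list[MedicationState], table: DosingTable) -> bool:
    """A line is exhausted when every agent on it is maxed or intolerant."""
    return bool(meds) and all(m.intolerant or m.at_max(table) for m in meds)


def _titratable(meds: list[MedicationState], table: DosingTable) -> Optional[MedicationState]:
    for m in meds:
        if not m.intolerant and not m.at_max(table):
            return m
    return None


def validate_regimen(regimen: list[MedicationState], table: DosingTable) -> None:
    raas = _raas_meds(regimen, table)
    classes = {table.agent(m.agent).drug_class for m in raas}
    if DrugClass.ARB in classes and DrugClass.ACEI in classes:
        raise ValueError("regimen carries both an ARB and an ACEI (one RAAS slot)")
    names = [m.agent for m in regimen]
    if len(set(names)) != len(names):
        raise ValueError("regimen lists the same agent twice")


def select_raas_agent(
    current_meds: list[MedicationState],
    table: Optional[DosingTable] = None,
) -> tuple[str, Action]:
    """Which RAAS agent to use when the RAAS slot is the indicated step.

    New starts get the program-default potent ARB. Patients already on
    losartan or on an ACEI other than lisinopril are switched to the
    potent ARB; lisinopril (once-daily ACEI) is titrated in place, as is
    an already-established potent ARB.
    """
    table = table or default_config()[1]
    raas = _raas_meds(current_meds, table)
    classes = {table.agent(m.agent).drug_class for m in raas}
    if DrugClass.ARB in classes and DrugClass.ACEI in classes:
        raise ValueError("patient is on both an ARB and an ACEI")
    if not raas:
        return table.default_arb, Action.START
    med = raas[0]
    entry = table.agent(med.agent)
    if entry.drug_class is DrugClass.ACEI and med.agent != "lisinopril":
        return table.default_arb, Action.SWITCH
    if entry.avoid:  # losartan: switch to a more potent ARB
        return table.default_arb, Action.SWITCH
    return med.agent, Action.TITRATE


# ---------------------------------------------------------------------------
# The decision engine
# ---------------------------------------------------------------------------

def _start_step(entry, conservative: bool) -> int:
    return entry.conservative_start_step if conservative else entry.standard_start_step


def _gated(
    rec: Recommendation,
    table: DosingTable,
    labs_latest: Optional[LabPanel],
    labs_baseline: Optional[LabPanel],
    t: Thresholds,
    as_of: Optional[dt.date],
    conservative: bool,
) -> Recommendation:
    """Apply the lab gate to a dosing recommendation; BLOCK becomes HOLD."""
    if rec.action not in DOSING_ACTIONS or rec.agent is None:
        return rec
    entry = table.agent(rec.agent)
    if not entry.requires_labs:
        return rec
    rec = rec.model_copy(update={"requires_lab_gate": True})
    gate = check_gate(entry.drug_class, labs_latest, labs_baseline, t, as_of)
    if gate.decision is GateDecision.BLOCK:
        return Recommendation(
            action=Action.HOLD,
            rationale_codes=["LAB_GATE_BLOCKED", *gate.codes],
            requires_lab_gate=True,
        )
    if gate.decision is GateDecision.PASS_CONSERVATIVE and rec.action in (
        Action.START, Action.ADD, Action.SWITCH,
    ):
        step = _start_step(entry, conservative=True)
        return rec.model_copy(
            update={"target_dose_step": step,
                    "rationale_codes": [*rec.rationale_codes, *gate.codes]}
        )
    if gate.codes:
        return rec.model_copy(
            update={"rationale_codes": [*rec.rationale_codes, *gate.codes]}
        )
    return rec


def _fourth_line(
    profile: PatientProfile,
    regimen: list[MedicationState],
    table: DosingTable,
    t: Thresholds,
    secondary_screen: Optional[SecondaryScreenPanel],
    labs_latest: Optional[LabPanel],
    labs_baseline: Optional[LabPanel],
    summary: Optional[WeeklyBPSummary],
    conservative: bool,
    as_of: Optional[dt.date],
) -> Recommendation:
    """Uncontrolled on a maximal conventional 3-drug regimen."""
    mras = _meds_of_class(regimen, DrugClass.MRA, table)
    bbs = _meds_of_class(regimen, DrugClass.BB, table)

    if not mras and not bbs:
        if secondary_screen is None:
            return Recommendation(
                action=Action.ORDER_SECONDARY_LABS,
                rationale_codes=["UNCONTROLLED_MAX_3DRUG"],
            )
        if secondary_screen.reviewed_positive:
            return Recommendation(
                action=Action.REFER_SPECIALIST,
                rationale_codes=["SECONDARY_SCREEN_POSITIVE"],
            )

    # MRA preferred when potassium permits
    target = _titratable(mras, table)
    if target is not None:
        return Recommendation(
            action=Action.TITRATE, agent=target.agent,
            target_dose_step=target.dose_step + 1,
            rationale_codes=["FOURTH_LINE_MRA"],
        )
    mra_exhausted = _line_exhausted(mras, table)
    if not mras:
        gate = check_gate(DrugClass.MRA, labs_latest, labs_baseline, t, as_of)
        if not gate.blocked:
            agent = "eplerenone" if (
                profile.sex is Sex.male and table.has_agent("eplerenone")
            ) else "spironolactone"
            entry = table.agent(agent)
            return Recommendation(
                action=Action.ADD, agent=agent,
                target_dose_step=_start_step(
                    entry, conservative or gate.decision is GateDecision.PASS_CONSERVATIVE
                ),
                rationale_codes=["FOURTH_LINE_MRA", *gate.codes],
            )
        mra_exhausted = True  # electrolytes do not permit; fall through to BB

    if mra_exhausted:
        target = _titratable(bbs, table)
        hr = summary.mean_hr if summary is not None else None
        if target is not None:
            if hr is not None and hr < t.hr_floor_bb:
                return Recommendation(
                    action=Action.PHYSICIAN_CONVERSATION,
                    rationale_codes=["HR_LT_55_BB"],
                )
            return Recommendation(
                action=Action.TITRATE, agent=target.agent,
                target_dose_step=target.dose_step + 1,
                rationale_codes=["FOURTH_LINE_BB"],
            )
        if not bbs:
            if hr is not None and hr < t.hr_floor_bb:
                return Recommendation(
                    action=Action.PHYSICIAN_CONVERSATION,
                    rationale_codes=["HR_LT_55_BB"],
                )
            agent = "metoprolol" if (
                profile.reactive_airway and table.has_agent("metoprolol")
            ) else "labetalol"
            entry = table.agent(agent)
            return Recommendation(
                action=Action.ADD, agent=agent,
                target_dose_step=_start_step(entry, conservative),
                rationale_codes=["FOURTH_LINE_BB"],
            )
    return Recommendation(
        action=Action.REFER_SPECIALIST, rationale_codes=["REGIMEN_EXHAUSTED"]
    )


def _escalate(
    profile: PatientProfile,
    pathway: Pathway,
    regimen: list[MedicationState],
    goal: GoalStatus,
    summary: Optional[WeeklyBPSummary],
    table: DosingTable,
    t: Thresholds,
    secondary_screen: Optional[SecondaryScreenPanel],
    labs_latest: Optional[LabPanel],
    labs_baseline: Optional[LabPanel],
    conservative: bool,
    as_of: Optional[dt.date],
) -> Recommendation:
    """Pick the next dosing step along the pathway's line sequence."""
    if pathway.kind is PathwayKind.CHILDBEARING:
        lines: list[DrugClass] = [DrugClass.CCB, DrugClass.BB]
    elif pathway.kind is PathwayKind.RAAS_FIRST:
        lines = [DrugClass.ARB, DrugClass.CCB, DrugClass.TD]  # ARB stands for RAAS slot
    else:
        lines = [DrugClass.CCB, DrugClass.ARB, DrugClass.TD]

    def class_meds(cls: DrugClass) -> list[MedicationState]:
        if cls in RAAS_CLASSES:
            return _raas_meds(regimen, table)
        return _meds_of_class(regimen, cls, table)

    for line_cls in lines:
        meds = class_meds(line_cls)
        target = _titratable(meds, table)
        if target is not None:
            # lisinopril/losartan handling: a switchable RAAS agent is
            # replaced rather than titrated
            if line_cls in RAAS_CLASSES:
                agent, action = select_raas_agent(regimen, table)
                if action is Action.SWITCH:
                    entry = table.agent(agent)
                    return Recommendation(
                        action=Action.SWITCH, agent=agent,
                        target_dose_step=_start_step(entry, conservative),
                        rationale_codes=["RAAS_SWITCH_POTENT_ARB"],
                    )
            return Recommendation(
                action=Action.TITRATE, agent=target.agent,
                target_dose_step=target.dose_step + 1,
                rationale_codes=["MAXIMIZE_BEFORE_ADD"],
            )
        if _line_exhausted(meds, table):
            # thiazide line: at max hydrochlorothiazide and close to goal,
            # chlorthalidone is the up-titration of the TD slot
            if line_cls is DrugClass.TD:
                on_chlorthalidone = any(m.agent == "chlorthalidone" for m in meds)
                hctz_maxed = any(
                    m.agent == "hydrochlorothiazide" and m.at_max(table)
                    and not m.intolerant for m in meds
                )
                if (hctz_maxed and not on_chlorthalidone
                        and goal.near_goal_within_margin):
                    entry = table.agent("chlorthalidone")
                    return Recommendation(
                        action=Action.SWITCH, agent="chlorthalidone",
                        target_dose_step=_start_step(entry, conservative),
                        rationale_codes=["CHLORTHALIDONE_SWITCH_NEAR_GOAL"],
                    )
            continue  # line done -> next line
        # line has no agent yet -> start/add it
        if line_cls in RAAS_CLASSES:
            agent, action = select_raas_agent(regimen, table)
            entry = table.agent(agent)
            return Recommendation(
                action=Action.ADD if regimen and action is Action.START else action,
                agent=agent,
                target_dose_step=_start_step(entry, conservative),
                rationale_codes=["PATHWAY_NEXT_LINE"],
            )
        if line_cls is DrugClass.TD:
            # hyponatremia contraindicates the thiazide line entirely
            if labs_latest is not None and labs_latest.na < t.na_min_td:
                continue
            agent = "hydrochlorothiazide"
        elif line_cls is DrugClass.BB:  # childbearing pathway second line
            hr = summary.mean_hr if summary is not None else None
            if hr is not None and hr < t.hr_floor_bb:
                return Recommendation(
                    action=Action.PHYSICIAN_CONVERSATION,
                    rationale_codes=["HR_LT_55_BB"],
                )
            agent = "labetalol"
        else:  # CCB line
            agent = next(
                a.name for a in table.agents_of_class(DrugClass.CCB) if not a.avoid
            )
        entry = table.agent(agent)
        return Recommendation(
            action=Action.ADD if regimen else Action.START, agent=agent,
            target_dose_step=_start_step(entry, conservative),
            rationale_codes=["PATHWAY_NEXT_LINE"],
        )

    if pathway.kind is PathwayKind.CHILDBEARING:
        return Recommendation(
            action=Action.REFER_SPECIALIST, rationale_codes=["REGIMEN_EXHAUSTED"]
        )
    return _fourth_line(
        profile, regimen, table, t, secondary_screen,
        labs_latest, labs_baseline, summary, conservative, as_of,
    )


def next_action(
    profile: PatientProfile,
    pathway: Pathway,
    regimen: list[MedicationState],
    goal: GoalStatus,
    summary: Optional[WeeklyBPSummary] = None,
    labs_latest: Optional[LabPanel] = None,
    labs_baseline: Optional[LabPanel] = None,
    as_of: Optional[dt.date] = None,
    secondary_screen: Optional[SecondaryScreenPanel] = None,
    thresholds: Optional[Thresholds] = None,
    dosing_table: Optional[DosingTable] = None,
) -> Recommendation:
    """The single next program step for one patient-week.

    Priority order: at goal -> hold; safety floor or heart rate < 55 on a
    beta blocker -> physician conversation; titration lockout (1 week,
    6 weeks for MRA) -> hold; medication-naive stage-1 low-ASCVD ->
    lifestyle trial; otherwise escalate along the pathway (titrate below
    max, add the next line, chlorthalidone switch near goal, secondary
    screen then MRA/BB fourth line, refer when exhausted). Lab-requiring
    steps are gated on the latest panel; a blocked gate holds.
    """
    if thresholds is None or dosing_table is None:
        default_t, default_table = default_config()
        thresholds = thresholds or default_t
        dosing_table = dosing_table or default_table
    t, table = thresholds, dosing_table
    validate_regimen(regimen, table)

    # (0) controlled: hold, maintenance pending labs
    if goal.at_goal:
        return Recommendation(action=Action.HOLD, rationale_codes=["AT_GOAL"])

    # (1) safety floors
    if goal.safety_floor_flag:
        return Recommendation(
            action=Action.PHYSICIAN_CONVERSATION, rationale_codes=["SAFETY_FLOOR_BP"]
        )
    hr = summary.mean_hr if summary is not None else None
    on_bb = any(
        table.agent(m.agent).drug_class is DrugClass.BB and not m.intolerant
        for m in regimen
    )
    if on_bb and hr is not None and hr < t.hr_floor_bb:
        return Recommendation(
            action=Action.PHYSICIAN_CONVERSATION, rationale_codes=["HR_LT_55_BB"]
        )

    # (2) titration lockout since the most recent regimen change
    if regimen and as_of is not None:
        last = max(regimen, key=lambda m: m.last_change_date)
        lockout = (
            t.titration_lockout_weeks_mra
            if table.agent(last.agent).drug_class is DrugClass.MRA
            else t.titration_lockout_weeks
        )
        weeks_since = (as_of - last.last_change_date).days / 7
        if weeks_since < lockout:
            return Recommendation(
                action=Action.HOLD, rationale_codes=["TITRATION_LOCKOUT"]
            )

    # (3) medication-naive stage-1 with low ASCVD risk: lifestyle first
    if (
        profile.medication_naive
        and not regimen
        and summary is not None
        and summary.mean_sbp is not None
        and summary.mean_sbp < t.stage2_sbp
        and summary.mean_dbp < t.stage2_dbp
        and profile.ascvd_risk_10yr is not None
        and profile.ascvd_risk_10yr < 0.10
    ):
        return Recommendation(
            action=Action.LIFESTYLE_TRIAL, rationale_codes=["STAGE1_LOW_ASCVD"]
        )

    conservative = pathway.covid_mode or profile.frail
    rec = _escalate(
        profile, pathway, regimen, goal, summary, table, t,
        secondary_screen, labs_latest, labs_baseline, conservative, as_of,
    )

    if pathway.covid_mode:
        rec = apply_covid_mode(
            rec, pathway.labs_available, goal, summary, regimen, t, table
        )
    return _gated(
        rec, table,
        labs_latest if pathway.labs_available else None,
        labs_baseline, t, as_of, conservative,
    )


def apply_covid_mode(
    recommendation: Recommendation,
    labs_available: bool,
    goal: GoalStatus,
    summary: Optional[WeeklyBPSummary] = None,
    regimen: Optional[list[MedicationState]] = None,
    thresholds: Optional[Thresholds] = None,
    dosing_table: Optional[DosingTable] = None,
) -> Recommendation:
    """Pandemic risk mitigation applied to a pending recommendation.

    Only dosing steps of lab-requiring classes are touched. With labs
    unreachable: above 140/90 the step is substituted with a lab-free
    agent (CCB first, labetalol once the CCB is maxed); below 140/90 a
    2-month lifestyle trial defers drug changes. With labs merely
    constrained, new starts use the conservative (one lower) step.
    """
    if thresholds is None or dosing_table is None:
        default_t, default_table = default_config()
        thresholds = thresholds or default_t
        dosing_table = dosing_table or default_table
    t, table = thresholds, dosing_table
    regimen = regimen or []

    rec = recommendation
    if rec.action not in DOSING_ACTIONS or rec.agent is None:
        return rec
    entry = table.agent(rec.agent)
    if entry.drug_class not in LAB_REQUIRING_CLASSES:
        return rec

    if labs_available:
        if rec.action in (Action.START, Action.ADD, Action.SWITCH):
            return rec.model_copy(
                update={"target_dose_step": _start_step(entry, conservative=True),
                        "rationale_codes": [*rec.rationale_codes, "COVID_CONSERVATIVE_DOSE"]}
            )
        return rec

    sbp = summary.mean_sbp if summary is not None else None
    dbp = summary.mean_dbp if summary is not None else None
    severe = (sbp is not None and sbp >= t.stage2_sbp) or (
        dbp is not None and dbp >= t.stage2_dbp
    )
    if not severe:
        return Recommendation(
            action=Action.LIFESTYLE_TRIAL,
            rationale_codes=["COVID_NO_LABS_BELOW_140_90"],
        )
    # substitute a lab-free class: CCB first, then labetalol
    ccbs = [m for m in regimen
            if table.agent(m.agent).drug_class is DrugClass.CCB]
    target = _titratable(ccbs, table)
    if target is not None:
        return Recommendation(
            action=Action.TITRATE, agent=target.agent,
            target_dose_step=target.dose_step + 1,
            rationale_codes=["COVID_SUBSTITUTE_LAB_FREE"],
        )
    if not ccbs:
        agent = next(a.name for a in table.agents_of_class(DrugClass.CCB) if not a.avoid)
        entry = table.agent(agent)
        return Recommendation(
            action=Action.ADD if regimen else Action.START, agent=agent,
            target_dose_step=_start_step(entry, conservative=True),
            rationale_codes=["COVID_SUBSTITUTE_LAB_FREE"],
        )
    hr = summary.mean_hr if summary is not None else None
    bbs = [m for m in regimen if table.agent(m.agent).drug_class is DrugClass.BB]
    target = _titratable(bbs, table)
    if target is not None or not bbs:
        if hr is not None and hr < t.hr_floor_bb:
            return Recommendation(
                action=Action.PHYSICIAN_CONVERSATION, rationale_codes=["HR_LT_55_BB"]
            )
    if target is not None:
        return Recommendation(
            action=Action.TITRATE, agent=target.agent,
            target_dose_step=target.dose_step + 1,
            rationale_codes=["COVID_SUBSTITUTE_LAB_FREE"],
        )
    if not bbs:
        entry = table.agent("labetalol")
        return Recommendation(
            action=Action.ADD, agent="labetalol",
            target_dose_step=_start_step(entry, conservative=True),
            rationale_codes=["COVID_SUBSTITUTE_LAB_FREE"],
        )
    return Recommendation(action=Action.HOLD, rationale_codes=["COVID_NO_LAB_FREE_OPTION"])


def consolidate_combo(
    regimen: list[MedicationState],
    as_of: dt.date,
    thresholds: Optional[Thresholds] = None,
    dosing_table: Optional[DosingTable] = None,
) -> Optional[Recommendation]:
    """Combination-pill consolidation for a maintenance regimen.

    When a thiazide and a RAAS blocker are both dose-stable (no change
    within the stability window) and a combination product exists for
    the pair, recommend consolidating; otherwise nothing.
    """
    if thresholds is None or dosing_table is None:
        default_t, default_table = default_config()
        thresholds = thresholds or default_t
        dosing_table = dosing_table or default_table
    t, table = thresholds, dosing_table

    def stable(m: MedicationState) -> bool:
        return (as_of - m.last_change_date).days >= t.combo_stable_weeks * 7

    raas = [m for m in _raas_meds(regimen, table) if stable(m) and not m.intolerant]
    tds = [m for m in _meds_of_class(regimen, DrugClass.TD, table)
           if stable(m) and not m.intolerant]
    for r in raas:
        for d in tds:
            combo = table.combo_for(r.agent, d.agent)
            if combo is not None:
                return Recommendation(
                    action=Action.CONSOLIDATE_COMBO, agent=combo.product,
                    rationale_codes=["COMBO_ADHERENCE"],
                )
    return None
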