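"""Synthetic cohort generator and closed-loop program simulator.

The published protocol contains no patient response model, so this
module supplies the statistical structure the engine's inputs must
have: home-BP streams with measurement noise and a white-coat offset on
office readings, a linear-additive dose-response (mmHg per dose step per
class, scaled by a patient-level lognormal sensitivity), and lab
trajectories that shift with RAAS/TD/MRA exposure. With noise switched
off the model inverts analytically, which is what makes the titration
logic testable against a closed form.

One pseudo-random stream per patient (master seed + patient index) keeps
trajectories independent of cohort edits.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .alerts import scan_critical
from .bp_monitoring import (
    GoalStatus,
    ProgramState,
    Sufficiency,
    WeeklyBPSummary,
    classify_transition,
    generate_schedule,
    goal_status,
    weekly_average,
)
from .core import (
    LAB_REQUIRING_CLASSES,
    RAAS_CLASSES,
    BPReading,
    DosingTable,
    DrugClass,
    LabPanel,
    LabRole,
    MedicationState,
    PatientProfile,
    ReadingContext,
    Sex,
    Thresholds,
    default_config,
)
from .pathway import (
    Action,
    DOSING_ACTIONS,
    Pathway,
    Recommendation,
    SecondaryScreenPanel,
    assign_pathway,
    next_action,
)

__all__ = [
    "SimParams", "SimPatient", "WeekRecord", "SimulationLog",
    "generate_cohort", "simulate_week", "run_program", "true_bp",
]


class ClassEffect(BaseModel):
    """Mean BP lowering per dose step for one drug class."""

    model_config = ConfigDict(frozen=True)

    sbp_per_step: float = Field(ge=0, description="mmHg SBP per dose step")
    dbp_fraction: float = Field(ge=0, le=1, default=0.5,
                                description="DBP drop as a fraction of the SBP drop")


class LabShift(BaseModel):
    """Per-dose-step analyte shifts induced by one drug class."""

    model_config = ConfigDict(frozen=True)

    k_per_step: float = 0.0
    na_per_step: float = 0.0
    creatinine_pct_per_step: float = 0.0
    egfr_per_step: float = 0.0


class SimParams(BaseModel):
    """Study-condition parameters for the synthetic cohort.

    Defaults describe a newly-enrolled uncontrolled-hypertension cohort:
    baseline home SBP ~ N(150, 12), DBP ~ N(92, 8); each dose step of a
    first-line agent lowers SBP ~5 mmHg on average (lognormal patient
    sensitivity, sigma 0.3); home readings carry N(0, 8) device/moment
    noise; office readings add a N(10, 6) white-coat offset.
    """

    n_patients: int = Field(default=100, gt=0)
    seed: int = Field(default=0, ge=0)

    baseline_sbp_mean: float = 150.0
    baseline_sbp_sd: float = Field(default=12.0, ge=0)
    baseline_dbp_mean: float = 92.0
    baseline_dbp_sd: float = Field(default=8.0, ge=0)

    class_effects: dict[DrugClass, ClassEffect] = Field(
        default_factory=lambda: {
            DrugClass.CCB: ClassEffect(sbp_per_step=5.0),
            DrugClass.ARB: ClassEffect(sbp_per_step=5.0),
            DrugClass.ACEI: ClassEffect(sbp_per_step=5.0),
            DrugClass.TD: ClassEffect(sbp_per_step=4.0),
            DrugClass.MRA: ClassEffect(sbp_per_step=4.0),
            DrugClass.BB: ClassEffect(sbp_per_step=4.0),
        }
    )
    sensitivity_sigma: float = Field(default=0.3, ge=0,
                                     description="lognormal sigma of per-patient response")
    measurement_noise_sd: float = Field(default=8.0, ge=0)
    white_coat_offset_mean: float = 10.0
    white_coat_offset_sd: float = Field(default=6.0, ge=0)
    adherence_prob: float = Field(default=0.9, ge=0, le=1)

    frail_prob: float = Field(default=0.15, ge=0, le=1)
    dm_prob: float = Field(default=0.25, ge=0, le=1)
    ckd_prob: float = Field(default=0.15, ge=0, le=1)
    childbearing_prob: float = Field(default=0.10, ge=0, le=1)
    reactive_airway_prob: float = Field(default=0.10, ge=0, le=1)
    secondary_positive_prob: float = Field(default=0.10, ge=0, le=1)

    lab_shifts: dict[DrugClass, LabShift] = Field(
        default_factory=lambda: {
            DrugClass.ARB: LabShift(k_per_step=0.10, creatinine_pct_per_step=4.0,
                                    egfr_per_step=-2.0),
            DrugClass.ACEI: LabShift(k_per_step=0.10, creatinine_pct_per_step=4.0,
                                     egfr_per_step=-2.0),
            DrugClass.TD: LabShift(k_per_step=-0.10, na_per_step=-0.8),
            DrugClass.MRA: LabShift(k_per_step=0.20),
        }
    )
    lab_noise_k_sd: float = Field(default=0.12, ge=0)
    lab_noise_na_sd: float = Field(default=1.0, ge=0)
    lab_noise_creat_sd: float = Field(default=0.05, ge=0)
    lab_noise_egfr_sd: float = Field(default=3.0, ge=0)

    include_ineligible: bool = False
    enrollment_date: dt.date = dt.date(2022, 1, 3)


class SimPatient(BaseModel):
    """One synthetic patient: profile, ground truth, and baseline data."""

    profile: PatientProfile
    baseline_labs: LabPanel
    office_history: list[BPReading]
    true_sbp: float
    true_dbp: float
    sensitivity: float
    white_coat_offset: float
    base_hr: float = 72.0


def _rng_for(params: SimParams, index: int) -> np.random.Generator:
    return np.random.default_rng(params.seed + index)


def true_bp(
    patient: SimPatient,
    regimen: list[MedicationState],
    params: SimParams,
    table: Optional[DosingTable] = None,
) -> tuple[float, float]:
    """Noise-free BP under the linear-additive dose-response model.

    Each tolerated agent at dose-step index ``s`` contributes
    ``effect * (s + 1) * sensitivity`` mmHg of SBP lowering (step index 0
    is one dose unit); DBP follows at the class's DBP fraction.
    """
    table = table or default_config()[1]
    sbp_drop = dbp_drop = 0.0
    for med in regimen:
        if med.intolerant:
            continue
        cls = table.agent(med.agent).drug_class
        effect = params.class_effects.get(cls)
        if effect is None:
            continue
        drop = effect.sbp_per_step * (med.dose_step + 1) * patient.sensitivity
        sbp_drop += drop
        dbp_drop += drop * effect.dbp_fraction
    return patient.true_sbp - sbp_drop, patient.true_dbp - dbp_drop


def generate_cohort(
    params: SimParams,
    thresholds: Optional[Thresholds] = None,
) -> list[SimPatient]:
    """Draw a cohort from the configured distributions.

    Patients are eligibility-eligible by construction (ages inside the
    program band, weight under the cuff limits, office BP above the
    inclusion cut-off) unless ``include_ineligible`` widens the draws
    for screening tests.
    """
    t = thresholds or default_config()[0]
    cohort: list[SimPatient] = []
    for i in range(params.n_patients):
        rng = _rng_for(params, i)
        sex = Sex.female if rng.random() < 0.5 else Sex.male
        childbearing = sex is Sex.female and rng.random() < params.childbearing_prob
        diabetes = rng.random() < params.dm_prob

        if params.include_ineligible:
            age = int(rng.integers(18, 95))
        elif childbearing:
            age = int(rng.integers(max(t.age_min, t.age_min_dm if diabetes else t.age_min),
                                   t.age_childbearing))
        else:
            lo = t.age_min_dm if diabetes else t.age_min
            age = int(rng.integers(max(lo, 45), t.age_max + 1))
        contraception = False if childbearing else (
            sex is Sex.female and age < t.age_childbearing
        )

        limit = t.weight_limit_female if sex is Sex.female else t.weight_limit_male
        weight = float(rng.uniform(120, limit + 40 if params.include_ineligible else limit))

        ckd = rng.random() < params.ckd_prob
        egfr = float(rng.uniform(35, 59) if ckd else rng.uniform(65, 105))
        labs = LabPanel(
            draw_date=params.enrollment_date - dt.timedelta(days=30),
            k=float(np.clip(rng.normal(4.1, 0.3), 3.3, 5.0)),
            na=float(np.clip(rng.normal(140, 2.0), 133, 146)),
            creatinine=float(np.clip(rng.normal(1.0, 0.2), 0.5, 2.5)),
            egfr=egfr,
            uacr=float(rng.lognormal(2.0, 1.0)),
            role=LabRole.baseline,
        )

        true_sbp = float(rng.normal(params.baseline_sbp_mean, params.baseline_sbp_sd))
        true_dbp = float(rng.normal(params.baseline_dbp_mean, params.baseline_dbp_sd))
        true_dbp = min(true_dbp, true_sbp - 25)
        wco = float(rng.normal(params.white_coat_offset_mean, params.white_coat_offset_sd))
        sensitivity = float(rng.lognormal(0.0, params.sensitivity_sigma))

        office: list[BPReading] = []
        for back in (5, 3, 1):  # months before enrollment
            ts = dt.datetime.combine(
                params.enrollment_date - dt.timedelta(days=30 * back),
                dt.time(10, 0),
            )
            sbp = true_sbp + wco + float(rng.normal(0, params.measurement_noise_sd))
            dbp = true_dbp + wco / 2 + float(rng.normal(0, params.measurement_noise_sd / 2))
            if not params.include_ineligible:
                sbp = max(sbp, 136.0)  # inclusion by construction
            sbp_i = int(round(sbp))
            dbp_i = int(round(min(dbp, sbp_i - 10)))
            office.append(BPReading(
                timestamp=ts, sbp=sbp_i, dbp=max(dbp_i, 40),
                context=ReadingContext.office,
            ))

        profile = PatientProfile(
            patient_id=f"sim-{i:04d}",
            age=age, sex=sex, weight=round(weight, 1),
            frail=bool(rng.random() < params.frail_prob),
            contraception=contraception,
            diabetes=diabetes,
            ascvd_risk_10yr=float(np.clip(rng.beta(2, 8), 0, 1)),
            medication_naive=True,
            reactive_airway=bool(rng.random() < params.reactive_airway_prob),
        )
        cohort.append(SimPatient(
            profile=profile, baseline_labs=labs, office_history=office,
            true_sbp=true_sbp, true_dbp=true_dbp, sensitivity=sensitivity,
            white_coat_offset=wco, base_hr=float(rng.normal(72, 6)),
        ))
    return cohort


def simulate_week(
    patient: SimPatient,
    regimen: list[MedicationState],
    week_start: dt.date,
    params: SimParams,
    rng: np.random.Generator,
    draw_labs: bool = False,
    table: Optional[DosingTable] = None,
) -> tuple[list[BPReading], Optional[LabPanel]]:
    """One monitored week: scheduled home readings, optionally a lab panel.

    Readings follow the 28-slot optimal schedule thinned by the
    adherence probability; values are the model's true BP plus
    measurement noise. Labs reflect the regimen's analyte shifts.
    """
    table = table or default_config()[1]
    sbp_true, dbp_true = true_bp(patient, regimen, params, table)
    hr_true = patient.base_hr
    for med in regimen:
        if not med.intolerant and table.agent(med.agent).drug_class is DrugClass.BB:
            hr_true -= 3.0 * (med.dose_step + 1)

    readings: list[BPReading] = []
    for slot in generate_schedule("optimal", week_start):
        if rng.random() >= params.adherence_prob:
            continue
        sbp = int(round(sbp_true + rng.normal(0, params.measurement_noise_sd)))
        dbp = int(round(dbp_true + rng.normal(0, params.measurement_noise_sd / 2)))
        sbp = max(sbp, 60)
        dbp = int(np.clip(dbp, 30, sbp - 5))
        hour = 8 if slot.session == "am" else 20
        readings.append(BPReading(
            timestamp=dt.datetime.combine(slot.date, dt.time(hour, 5 * slot.replicate)),
            sbp=sbp, dbp=dbp,
            hr=max(int(round(hr_true + rng.normal(0, 3))), 30),
            context=ReadingContext.home,
        ))

    labs: Optional[LabPanel] = None
    if draw_labs:
        base = patient.baseline_labs
        k, na, creat, egfr = base.k, base.na, base.creatinine, base.egfr
        for med in regimen:
            if med.intolerant:
                continue
            shift = params.lab_shifts.get(table.agent(med.agent).drug_class)
            if shift is None:
                continue
            units = med.dose_step + 1
            k += shift.k_per_step * units
            na += shift.na_per_step * units
            creat *= (1 + shift.creatinine_pct_per_step / 100) ** units
            egfr += shift.egfr_per_step * units
        labs = LabPanel(
            draw_date=week_start,
            k=max(k + float(rng.normal(0, params.lab_noise_k_sd)), 2.5),
            na=max(na + float(rng.normal(0, params.lab_noise_na_sd)), 120),
            creatinine=max(creat + float(rng.normal(0, params.lab_noise_creat_sd)), 0.3),
            egfr=max(egfr + float(rng.normal(0, params.lab_noise_egfr_sd)), 5),
            role=LabRole.followup,
        )
    return readings, labs


# ---------------------------------------------------------------------------
# Closed program loop
# ---------------------------------------------------------------------------

class WeekRecord(BaseModel):
    patient_id: str
    week: int
    state: ProgramState
    summary: WeeklyBPSummary
    goal: Optional[GoalStatus] = None
    recommendation: Optional[Recommendation] = None
    n_alerts: int = 0
    regimen: list[tuple[str, int]] = []  # (agent, dose step) snapshot after apply


class SimulationLog(BaseModel):
    params_seed: int
    n_patients: int
    weeks: int
    records: list[WeekRecord]
    time_to_maintenance: dict[str, Optional[int]]

    def fraction_at_goal_by_week(self) -> list[float]:
        out = []
        for w in range(self.weeks):
            recs = [r for r in self.records if r.week == w and r.goal is not None]
            if not recs:
                out.append(float("nan"))
                continue
            out.append(sum(1 for r in recs if r.goal.at_goal) / len(recs))
        return out


def _apply(
    rec: Recommendation,
    regimen: list[MedicationState],
    effective: dt.date,
    table: DosingTable,
) -> list[MedicationState]:
    """Apply a dosing recommendation; changes dated at *effective*."""
    if rec.action not in DOSING_ACTIONS:
        return regimen
    new = [m.model_copy() for m in regimen]
    if rec.action is Action.TITRATE:
        for m in new:
            if m.agent == rec.agent:
                m.dose_step = rec.target_dose_step
                m.last_change_date = effective
        return new
    if rec.action is Action.SWITCH:
        new_cls = table.agent(rec.agent).drug_class
        drop = RAAS_CLASSES if new_cls in RAAS_CLASSES else {new_cls}
        new = [m for m in new if table.agent(m.agent).drug_class not in drop]
    new.append(MedicationState(
        agent=rec.agent, dose_step=rec.target_dose_step,
        start_date=effective, last_change_date=effective,
    ))
    return new


def run_program(
    params: SimParams,
    max_weeks: int = 26,
    thresholds: Optional[Thresholds] = None,
    dosing_table: Optional[DosingTable] = None,
) -> SimulationLog:
    """Run the full weekly loop for a synthetic cohort.

    Each week: simulate readings, aggregate, classify the program state,
    invoke the engine, and apply any dosing change at the start of the
    next week. A patient stops at maintenance (including white-coat),
    referral, or ``max_weeks``.
    """
    if thresholds is None or dosing_table is None:
        d_t, d_table = default_config()
        thresholds = thresholds or d_t
        dosing_table = dosing_table or d_table
    t, table = thresholds, dosing_table

    cohort = generate_cohort(params, t)
    records: list[WeekRecord] = []
    ttm: dict[str, Optional[int]] = {}

    for i, patient in enumerate(cohort):
        # separate stream from the cohort draw so trajectory randomness
        # does not depend on how many cohort-level variates were consumed
        rng = np.random.default_rng(params.seed + i + 10_000_019)
        state = ProgramState.enrolled_baseline
        regimen: list[MedicationState] = []
        latest_labs = patient.baseline_labs
        screen_result: Optional[SecondaryScreenPanel] = None
        any_change = False
        last_change_week: Optional[int] = None
        lab_due_week: Optional[int] = None
        lifestyle_until: Optional[int] = None
        pathway = assign_pathway(patient.profile, patient.baseline_labs,
                                 thresholds=t)
        ttm[patient.profile.patient_id] = None

        for week in range(max_weeks):
            week_start = params.enrollment_date + dt.timedelta(weeks=week)
            draw = lab_due_week is not None and week >= lab_due_week
            readings, labs = simulate_week(
                patient, regimen, week_start, params, rng, draw_labs=draw, table=table
            )
            if labs is not None:
                latest_labs = labs
                lab_due_week = None
            summary = weekly_average(readings, week_start, t)
            n_alerts = len(scan_critical(
                readings, week_start + dt.timedelta(days=6), t
            ))

            weeks_since = (
                float(week - last_change_week) if last_change_week is not None else math.inf
            )
            state = classify_transition(
                state, summary, patient.profile.frail, any_change, weeks_since, t
            )
            record = WeekRecord(
                patient_id=patient.profile.patient_id, week=week, state=state,
                summary=summary, n_alerts=n_alerts,
                regimen=[(m.agent, m.dose_step) for m in regimen],
            )

            if state in (ProgramState.maintenance, ProgramState.white_coat):
                if ttm[patient.profile.patient_id] is None:
                    ttm[patient.profile.patient_id] = week
                records.append(record)
                break
            if summary.sufficiency is Sufficiency.insufficient:
                records.append(record)
                continue
            if lifestyle_until is not None and week < lifestyle_until:
                records.append(record)
                continue

            goal = goal_status(summary, patient.profile.frail, t)
            profile = patient.profile.model_copy(
                update={"current_meds": regimen, "medication_naive": not any_change}
            )
            rec = next_action(
                profile, pathway, regimen, goal, summary,
                latest_labs, patient.baseline_labs,
                as_of=week_start + dt.timedelta(days=7),
                secondary_screen=screen_result,
                thresholds=t, dosing_table=table,
            )
            record.goal = goal
            record.recommendation = rec

            if rec.action is Action.ORDER_SECONDARY_LABS:
                screen_result = SecondaryScreenPanel(
                    reviewed_positive=bool(rng.random() < params.secondary_positive_prob)
                )
            elif rec.action is Action.LIFESTYLE_TRIAL:
                lifestyle_until = week + 4 * t.lifestyle_trial_months
            elif rec.action is Action.REFER_SPECIALIST:
                state = ProgramState.referred
                record.state = state
            elif rec.action in DOSING_ACTIONS:
                effective = week_start + dt.timedelta(weeks=1)
                regimen = _apply(rec, regimen, effective, table)
                any_change = True
                last_change_week = week + 1
                if table.agent(rec.agent).drug_class in LAB_REQUIRING_CLASSES:
                    lab_due_week = week + 2  # 1-2 week post-change window
            record.regimen = [(m.agent, m.dose_step) for m in regimen]
            records.append(record)
            if state is ProgramState.referred:
                break

    return SimulationLog(
        params_seed=params.seed, n_patients=params.n_patients,
        weeks=max_weeks, records=records, time_to_maintenance=ttm,
    )
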