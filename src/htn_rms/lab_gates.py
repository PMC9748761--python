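"""Per-drug-class laboratory gating and lab-draw scheduling.

CCBs and BBs need only the general enrolment labs; ARB/ACEI, TD and MRA
starts and titrations are gated on the most recent basic metabolic
panel. Gates use the printed comparisons verbatim: a RAAS blocker is
blocked at K >= 5.2 mmol/L (i.e. "most recent K < 5.2" must hold),
eGFR < 30, or an eGFR fall of >= 30% from the enrolment baseline; a
thiazide at K < 3.5, Na < 135 or eGFR < 30; an MRA combines both sets
and additionally starts at the conservative dose when 4.5 < K < 5.2.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .core import (
    LAB_REQUIRING_CLASSES,
    AgentEntry,
    DrugClass,
    LabPanel,
    Thresholds,
    default_config,
)


class GateDecision(str, Enum):
    PASS = "PASS"
    PASS_CONSERVATIVE = "PASS_CONSERVATIVE"
    BLOCK = "BLOCK"


class GateResult(BaseModel):
    decision: GateDecision
    codes: list[str]

    @property
    def blocked(self) -> bool:
        return self.decision is GateDecision.BLOCK


class LabScheduleReason(str, Enum):
    post_initiation = "post_initiation"
    post_titration = "post_titration"
    every_other_titration = "every_other_titration"
    final_dose = "final_dose"
    repeat_trigger = "repeat_trigger"


class LabSchedule(BaseModel):
    next_draw_window: Optional[tuple[dt.date, dt.date]]
    reason: LabScheduleReason

    @model_validator(mode="after")
    def _window_ordered(self) -> "LabSchedule":
        if self.next_draw_window is not None:
            lo, hi = self.next_draw_window
            if lo > hi:
                raise ValueError("draw window must be (earliest, latest)")
        return self


class RepeatAction(str, Enum):
    NONE = "NONE"
    REPEAT_LABS = "REPEAT_LABS"
    DOWN_TITRATE = "DOWN_TITRATE"


def _baseline_stale(
    baseline: Optional[LabPanel], as_of: Optional[dt.date], t: Thresholds
) -> bool:
    if baseline is None or as_of is None:
        return False
    age_days = (as_of - baseline.draw_date).days
    return age_days > t.baseline_lab_max_age_months * 30.44


def check_gate(
    drug_class: DrugClass,
    latest: Optional[LabPanel],
    baseline: Optional[LabPanel] = None,
    thresholds: Optional[Thresholds] = None,
    as_of: Optional[dt.date] = None,
) -> GateResult:
    """Gate an initiation or titration of *drug_class* on the latest panel.

    CCB/BB pass vacuously. For lab-requiring classes a missing panel
    blocks. Warning codes (RAAS with eGFR < 60 or K > 4.5; TD with
    Na < 140 or K < 4.2) may accompany a PASS; they never soften a BLOCK.
    """
    t = thresholds or default_config()[0]
    if drug_class not in LAB_REQUIRING_CLASSES:
        return GateResult(decision=GateDecision.PASS, codes=[])
    if latest is None:
        return GateResult(decision=GateDecision.BLOCK, codes=["NO_RECENT_PANEL"])

    codes: list[str] = []
    blocked = False
    if _baseline_stale(baseline, as_of, t):
        codes.append("STALE_BASELINE")
        baseline = None

    egfr_dropped = (
        baseline is not None
        and latest.egfr <= baseline.egfr * (1 - t.egfr_drop_pct / 100)
    )

    if drug_class.is_raas:
        if latest.k >= t.k_max_raas:
            blocked = True
            codes.append("K_GE_5_2")
        if latest.egfr < t.egfr_min:
            blocked = True
            codes.append("EGFR_LT_30")
        if egfr_dropped:
            blocked = True
            codes.append("EGFR_DROP_30PCT")
        if not blocked:
            if latest.egfr < t.egfr_raas_pathway:
                codes.append("EGFR_LT_60_WARN")
            if latest.k > t.k_warn_raas:
                codes.append("K_WARN_GT_4_5")
        return GateResult(
            decision=GateDecision.BLOCK if blocked else GateDecision.PASS, codes=codes
        )

    if drug_class is DrugClass.TD:
        if latest.k < t.k_min_td:
            blocked = True
            codes.append("K_LT_3_5")
        if latest.na < t.na_min_td:
            blocked = True
            codes.append("NA_LT_135")
        if latest.egfr < t.egfr_min:
            blocked = True
            codes.append("EGFR_LT_30")
        if not blocked:
            if latest.na < t.na_warn_td:
                codes.append("NA_WARN_LT_140")
            if latest.k < t.k_warn_td:
                codes.append("K_WARN_LT_4_2")
        return GateResult(
            decision=GateDecision.BLOCK if blocked else GateDecision.PASS, codes=codes
        )

    # MRA
    if latest.k >= t.k_max_raas:
        blocked = True
        codes.append("K_GE_5_2")
    if latest.na < t.na_min_td:
        blocked = True
        codes.append("NA_LT_135")
    if latest.egfr < t.egfr_min:
        blocked = True
        codes.append("EGFR_LT_30")
    if egfr_dropped:
        blocked = True
        codes.append("EGFR_DROP_30PCT")
    if blocked:
        return GateResult(decision=GateDecision.BLOCK, codes=codes)
    if latest.k > t.k_warn_raas:
        codes.append("K_GT_4_5_CONSERVATIVE_DISCUSS_LEAD")
        return GateResult(decision=GateDecision.PASS_CONSERVATIVE, codes=codes)
    return GateResult(decision=GateDecision.PASS, codes=codes)


def repeat_or_downtitrate(
    drug_class: DrugClass,
    latest: LabPanel,
    baseline: LabPanel,
    prior_repeat_confirmed: bool = False,
    thresholds: Optional[Thresholds] = None,
) -> RepeatAction:
    """Post-titration lab surveillance: repeat the draw or step back down.

    Triggers on a creatinine rise >= 30% from baseline for any gated
    class; for RAAS/MRA additionally on a K rise >= 15% from baseline
    conjoined with K > 5.0 mmol/L (both conjuncts required); for TD/MRA
    on K < 3.5 or Na < 135. The first trigger asks for repeat labs; a
    trigger that a repeat draw has already confirmed steps the regimen
    back down one step and rechecks.
    """
    t = thresholds or default_config()[0]
    triggered = latest.creatinine >= baseline.creatinine * (1 + t.creat_rise_pct / 100)
    if drug_class.is_raas or drug_class is DrugClass.MRA:
        k_rise = (latest.k - baseline.k) / baseline.k * 100
        if k_rise >= t.k_rise_pct and latest.k > t.k_abs_for_rise:
            triggered = True
    if drug_class in (DrugClass.TD, DrugClass.MRA):
        if latest.na < t.na_min_td:
            triggered = True
    if drug_class is DrugClass.TD and latest.k < t.k_min_td:
        triggered = True
    if not triggered:
        return RepeatAction.NONE
    return RepeatAction.DOWN_TITRATE if prior_repeat_confirmed else RepeatAction.REPEAT_LABS


def schedule_labs(
    agent: AgentEntry,
    change_date: dt.date,
    change_number: int,
    at_final_dose: bool,
    previous_labs_wnl: bool = False,
    thresholds: Optional[Thresholds] = None,
) -> Optional[LabSchedule]:
    """Next lab-draw window after a dose change of *agent*.

    ``change_number`` counts dose changes for this agent (0 = initiation).
    Draws fall 1-2 weeks after initiation and after each titration; with
    three or more steps on the ladder and previous values within normal
    limits, intermediate titrations alternate (every-other cadence, the
    skipped draw deferred to the next change). The final-dose draw is
    never skipped and may fall anywhere within 4 weeks of the change.
    Lab-free agents (CCB/BB) have no schedule.
    """
    t = thresholds or default_config()[0]
    if not agent.requires_labs:
        return None
    if at_final_dose:
        return LabSchedule(
            next_draw_window=(
                change_date,
                change_date + dt.timedelta(weeks=t.final_lab_window_weeks),
            ),
            reason=LabScheduleReason.final_dose,
        )
    lo, hi = t.post_titration_lab_window_weeks
    window = (
        change_date + dt.timedelta(weeks=lo),
        change_date + dt.timedelta(weeks=hi),
    )
    if change_number == 0:
        return LabSchedule(next_draw_window=window, reason=LabScheduleReason.post_initiation)
    if len(agent.steps) >= 3 and previous_labs_wnl and change_number % 2 == 1:
        # skip this draw; next change (or final dose) picks it up
        return LabSchedule(
            next_draw_window=None, reason=LabScheduleReason.every_other_titration
        )
    return LabSchedule(next_draw_window=window, reason=LabScheduleReason.post_titration)


def program_warnings(
    pending_class: Optional[DrugClass],
    latest: Optional[LabPanel],
    baseline: Optional[LabPanel] = None,
    thresholds: Optional[Thresholds] = None,
) -> list[str]:
    """Program-level warnings attached to a pending recommendation.

    Five rules, evaluated against the class of the pending agent:
    RAAS with eGFR < 60; RAAS with K > 4.5; TD with Na < 140; TD with
    K < 4.2; RAAS or TD with a K rise > 15% from the enrolment baseline
    conjoined with most recent K > 5 mmol/L (strict, as printed for this
    program-level rule).
    """
    t = thresholds or default_config()[0]
    if pending_class is None or latest is None:
        return []
    warnings: list[str] = []
    if pending_class.is_raas:
        if latest.egfr < t.egfr_raas_pathway:
            warnings.append("RAAS_EGFR_LT_60")
        if latest.k > t.k_warn_raas:
            warnings.append("RAAS_K_GT_4_5")
    if pending_class is DrugClass.TD:
        if latest.na < t.na_warn_td:
            warnings.append("TD_NA_LT_140")
        if latest.k < t.k_warn_td:
            warnings.append("TD_K_LT_4_2")
    if (pending_class.is_raas or pending_class is DrugClass.TD) and baseline is not None:
        k_rise = (latest.k - baseline.k) / baseline.k * 100
        if k_rise > t.k_rise_pct and latest.k > t.k_abs_for_rise:
            warnings.append("K_RISE_GT_15PCT_AND_GT_5")
    return warnings
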