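"""Daily critical-value scanning and alarm-symptom triage.

Single-day rules: any reading with SBP <= 90, DBP >= 120 or SBP >= 200.
Rolling 7-day rules: 2 distinct days with SBP >= 190, or 3 distinct days
with SBP >= 180. A "day" is the local calendar date of the reading; one
crossing reading qualifies the whole day. Alarm symptoms (chest pain,
acute dyspnoea, severe headache, oropharyngeal swelling, unclear
thinking, visual changes, nausea/vomiting) always mean: call EMS and
notify the clinical leads.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .core import BPReading, Thresholds, default_config


class AlertType(str, Enum):
    LOW_SBP_90 = "LOW_SBP_90"
    HIGH_DBP_120 = "HIGH_DBP_120"
    HIGH_SBP_200 = "HIGH_SBP_200"
    SBP_190_X2 = "SBP_190_X2"
    SBP_180_X3 = "SBP_180_X3"


MULTI_DAY_ALERTS = frozenset({AlertType.SBP_190_X2, AlertType.SBP_180_X3})


class Instruction(str, Enum):
    RECHECK_1H = "RECHECK_1H"
    CALL_PROGRAM = "CALL_PROGRAM"
    CALL_EMS = "CALL_EMS"
    CLINICIAN_TRIAGE = "CLINICIAN_TRIAGE"


class AlarmSymptom(str, Enum):
    chest_pain = "chest_pain"
    acute_shortness_of_breath = "acute_shortness_of_breath"
    severe_headache = "severe_headache"
    oropharyngeal_swelling = "oropharyngeal_swelling"
    unclear_thinking = "unclear_thinking"
    visual_changes = "visual_changes"
    nausea_vomiting = "nausea_vomiting"


class SymptomTriage(str, Enum):
    CALL_EMS_AND_NOTIFY = "CALL_EMS_AND_NOTIFY"
    none = "none"


class AlertEvent(BaseModel):
    alert_type: AlertType
    trigger_dates: list[dt.date]
    window: tuple[dt.date, dt.date]

    @model_validator(mode="after")
    def _validate(self) -> "AlertEvent":
        if len(set(self.trigger_dates)) != len(self.trigger_dates):
            raise ValueError("trigger_dates must be distinct calendar dates")
        lo, hi = self.window
        if any(not lo <= d <= hi for d in self.trigger_dates):
            raise ValueError("trigger_dates must fall within window")
        minimum = {AlertType.SBP_190_X2: 2, AlertType.SBP_180_X3: 3}.get(self.alert_type, 1)
        if len(self.trigger_dates) < minimum:
            raise ValueError(
                f"{self.alert_type.value} requires >= {minimum} trigger dates"
            )
        return self


def scan_critical(
    readings: list[BPReading],
    as_of: dt.date,
    thresholds: Optional[Thresholds] = None,
) -> list[AlertEvent]:
    """Scan the trailing 7-day window ending at *as_of* for critical values.

    Emits one single-day event per (rule, date) and at most one of each
    multi-day event per window. A 200-mmHg reading also counts toward
    the 190- and 180-threshold day counts.
    """
    t = thresholds or default_config()[0]
    window_start = as_of - dt.timedelta(days=t.alert_window_days - 1)
    window = (window_start, as_of)
    in_window = [r for r in readings if window_start <= r.timestamp.date() <= as_of]

    events: list[AlertEvent] = []
    single_day_rules = [
        (AlertType.LOW_SBP_90, lambda r: r.sbp <= t.alert_low_sbp),
        (AlertType.HIGH_DBP_120, lambda r: r.dbp >= t.alert_high_dbp),
        (AlertType.HIGH_SBP_200, lambda r: r.sbp >= t.alert_high_sbp),
    ]
    for alert_type, rule in single_day_rules:
        for day in sorted({r.timestamp.date() for r in in_window if rule(r)}):
            events.append(
                AlertEvent(alert_type=alert_type, trigger_dates=[day], window=window)
            )

    multi_day_rules = [
        (AlertType.SBP_190_X2, t.alert_sbp_190, t.alert_sbp_190_days),
        (AlertType.SBP_180_X3, t.alert_sbp_180, t.alert_sbp_180_days),
    ]
    for alert_type, cutoff, min_days in multi_day_rules:
        days = sorted({r.timestamp.date() for r in in_window if r.sbp >= cutoff})
        if len(days) >= min_days:
            events.append(
                AlertEvent(alert_type=alert_type, trigger_dates=days, window=window)
            )
    return events


def patient_instruction(
    event: AlertEvent,
    symptomatic_dizziness: bool = False,
    persisted_after_recheck: bool = False,
) -> Instruction:
    """The pamphlet instruction attached to one alert event.

    An isolated SBP >= 200 without alarm symptoms, or SBP <= 90 with
    dizziness/lightheadedness, earns a 1-hour recheck; persistence after
    the recheck means call the program. Everything else — including the
    multi-day report-level rules — is triaged by the clinician team.
    """
    if event.alert_type in MULTI_DAY_ALERTS:
        return Instruction.CLINICIAN_TRIAGE
    if event.alert_type is AlertType.HIGH_SBP_200:
        return Instruction.CALL_PROGRAM if persisted_after_recheck else Instruction.RECHECK_1H
    if event.alert_type is AlertType.LOW_SBP_90 and symptomatic_dizziness:
        return Instruction.CALL_PROGRAM if persisted_after_recheck else Instruction.RECHECK_1H
    return Instruction.CLINICIAN_TRIAGE


def triage_symptoms(symptoms: list[AlarmSymptom]) -> SymptomTriage:
    """EMS triage for reported alarm symptoms (closed enumeration).

    Any alarm symptom means call EMS with immediate notification of the
    program clinical leads and pharmacist.
    """
    validated = [AlarmSymptom(s) for s in symptoms]  # unknown string -> ValueError
    if validated:
        return SymptomTriage.CALL_EMS_AND_NOTIFY
    return SymptomTriage.none
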