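"""Program inclusion/exclusion screening.

Inclusion fires on either the single most recent office BP (within
6 months) or the mean of the three most recent office readings (within
18 months). Exclusion codes cover age range, pregnancy, HFrEF, severe
aortic stenosis, bilateral renal artery stenosis, eGFR < 30, orthostatic
hypotension (problem-list flag or postural test), terminal condition,
inability to consent, cuff weight limits, and a controlled 24-h ABPM
within the past year.
"""

from __future__ import annotations

import datetime as dt
import logging
from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .core import (
    BPReading,
    LabPanel,
    PatientProfile,
    ReadingContext,
    Sex,
    Thresholds,
    default_config,
)

logger = logging.getLogger(__name__)


class InclusionRule(str, Enum):
    recent_office_bp = "recent_office_bp"
    mean_of_three = "mean_of_three"
    none = "none"


class ExclusionCode(str, Enum):
    AGE_RANGE = "AGE_RANGE"
    PREGNANT = "PREGNANT"
    HFrEF = "HFrEF"
    AORTIC_STENOSIS = "AORTIC_STENOSIS"
    RAS_BILATERAL = "RAS_BILATERAL"
    EGFR_LT_30 = "EGFR_LT_30"
    OH = "OH"
    TERMINAL = "TERMINAL"
    CONSENT = "CONSENT"
    WEIGHT_CUFF = "WEIGHT_CUFF"
    CONTROLLED_ABPM = "CONTROLLED_ABPM"


class EligibilityResult(BaseModel):
    eligible: bool
    inclusion_rule_fired: InclusionRule
    exclusion_codes: list[ExclusionCode]

    @model_validator(mode="after")
    def _consistent(self) -> "EligibilityResult":
        expect = (
            self.inclusion_rule_fired is not InclusionRule.none
            and not self.exclusion_codes
        )
        if self.eligible != expect:
            raise ValueError("eligible must equal (inclusion fired and no exclusions)")
        return self


def _months_before(as_of: dt.date, months: int) -> dt.date:
    """Calendar-month subtraction, clamping the day into the target month."""
    y, m = divmod((as_of.year * 12 + as_of.month - 1) - months, 12)
    m += 1
    day = min(as_of.day, [31, 29 if y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)
                          else 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1])
    return dt.date(y, m, day)


def assess_inclusion(
    office_bps: list[BPReading],
    as_of: dt.date,
    thresholds: Optional[Thresholds] = None,
) -> InclusionRule:
    """Which office-BP inclusion rule (if any) a history satisfies at *as_of*.

    Rule 1: the single most recent office reading, if within 6 months, has
    SBP >= 135 or DBP >= 85. Rule 2: the arithmetic means of the SBPs
    and/or DBPs of the three most recent readings within 18 months cross
    the same cut-offs. The thresholds are the frail BP goals: enrolment
    targets patients above the most permissive program goal.
    """
    t = thresholds or default_config()[0]
    if not office_bps:
        return InclusionRule.none
    # ties in visit dates broken by record order (stable sort), with warning
    dates = [r.timestamp for r in office_bps]
    if len(set(dates)) != len(dates):
        logger.warning("office-BP history has tied visit dates; record order breaks ties")
    history = sorted(
        (r for r in office_bps if r.timestamp.date() <= as_of),
        key=lambda r: r.timestamp,
    )
    if not history:
        return InclusionRule.none

    most_recent = history[-1]
    if most_recent.timestamp.date() >= _months_before(as_of, t.office_recent_months):
        if most_recent.sbp >= t.goal_sbp_frail or most_recent.dbp >= t.goal_dbp_frail:
            return InclusionRule.recent_office_bp

    window_start = _months_before(as_of, t.office_mean_months)
    recent3 = [r for r in history if r.timestamp.date() >= window_start][-3:]
    if len(recent3) == 3:
        mean_sbp = sum(r.sbp for r in recent3) / 3
        mean_dbp = sum(r.dbp for r in recent3) / 3
        if mean_sbp >= t.goal_sbp_frail or mean_dbp >= t.goal_dbp_frail:
            return InclusionRule.mean_of_three
    return InclusionRule.none


def assess_exclusions(
    profile: PatientProfile,
    labs: Optional[LabPanel] = None,
    abpm_controlled_within_year: bool = False,
    thresholds: Optional[Thresholds] = None,
) -> list[ExclusionCode]:
    """Every exclusion code applicable to a candidate.

    Missing optional inputs (labs, ABPM result) simply suppress the
    corresponding rule. The age floor rises from 26 to 40 for patients
    with diabetes; cuff weight limits are sex-specific.
    """
    t = thresholds or default_config()[0]
    codes: list[ExclusionCode] = []

    age_floor = t.age_min_dm if profile.diabetes else t.age_min
    if profile.age < age_floor or profile.age > t.age_max:
        codes.append(ExclusionCode.AGE_RANGE)
    if profile.pregnant_or_breastfeeding:
        codes.append(ExclusionCode.PREGNANT)
    if profile.heart_failure_reduced_EF:
        codes.append(ExclusionCode.HFrEF)
    if profile.severe_aortic_stenosis:
        codes.append(ExclusionCode.AORTIC_STENOSIS)
    if profile.bilateral_renal_artery_stenosis:
        codes.append(ExclusionCode.RAS_BILATERAL)
    if labs is not None and labs.egfr < t.egfr_min:
        codes.append(ExclusionCode.EGFR_LT_30)
    if profile.orthostatic_hypotension:
        codes.append(ExclusionCode.OH)
    if profile.terminal_condition:
        codes.append(ExclusionCode.TERMINAL)
    if not profile.can_consent:
        codes.append(ExclusionCode.CONSENT)
    weight_limit = (
        t.weight_limit_female if profile.sex is Sex.female else t.weight_limit_male
    )
    if profile.weight > weight_limit:
        codes.append(ExclusionCode.WEIGHT_CUFF)
    if abpm_controlled_within_year:
        codes.append(ExclusionCode.CONTROLLED_ABPM)
    return codes


def postural_oh_test(
    seated: BPReading,
    standing: BPReading,
    thresholds: Optional[Thresholds] = None,
) -> bool:
    """Orthostatic hypotension on a seated-to-standing postural check.

    True iff SBP dropped by >= 20 mmHg or DBP by >= 10 mmHg on standing
    (inclusive at the boundary, the standard OH definition).
    """
    if seated.context is not ReadingContext.seated:
        raise ValueError(f"seated reading has context {seated.context.value!r}")
    if standing.context is not ReadingContext.standing:
        raise ValueError(f"standing reading has context {standing.context.value!r}")
    t = thresholds or default_config()[0]
    return (
        seated.sbp - standing.sbp >= t.oh_sbp_drop
        or seated.dbp - standing.dbp >= t.oh_dbp_drop
    )


def screen(
    profile: PatientProfile,
    office_bps: list[BPReading],
    as_of: dt.date,
    labs: Optional[LabPanel] = None,
    abpm_controlled_within_year: bool = False,
    thresholds: Optional[Thresholds] = None,
) -> EligibilityResult:
    """Full eligibility screen: inclusion rules plus exclusion codes."""
    rule = assess_inclusion(office_bps, as_of, thresholds)
    codes = assess_exclusions(profile, labs, abpm_controlled_within_year, thresholds)
    return EligibilityResult(
        eligible=rule is not InclusionRule.none and not codes,
        inclusion_rule_fired=rule,
        exclusion_codes=codes,
    )
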