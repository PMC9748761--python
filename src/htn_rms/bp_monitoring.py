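"""Home-BP schedule, weekly aggregation, goal classification, program states.

The home monitoring protocol is twice-daily duplicate seated readings:
7 days / 28 readings is the optimal week, 3 days / 12 readings the
minimal acceptable one. The weekly mean per channel is taken after
removing values more than 3 sample-SD from the channel mean (one pass,
per channel — an outlying systolic value does not discard its paired
diastolic). Goal status compares the weekly means to the program goal
(<130/80, relaxed to <135/85 with frailty).
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from enum import Enum
from typing import Optional

from pydantic import BaseModel

from .core import BPReading, Thresholds, default_config

logger = logging.getLogger(__name__)


class Sufficiency(str, Enum):
    optimal = "optimal"
    minimal = "minimal"
    insufficient = "insufficient"


class ProgramState(str, Enum):
    enrolled_baseline = "enrolled_baseline"
    active_titration = "active_titration"
    maintenance = "maintenance"
    white_coat = "white_coat"
    referred = "referred"
    withdrawn = "withdrawn"


class WeeklyBPSummary(BaseModel):
    window_start: dt.date
    n_readings: int
    n_excluded_sbp: int = 0
    n_excluded_dbp: int = 0
    mean_sbp: Optional[float] = None
    mean_dbp: Optional[float] = None
    mean_hr: Optional[float] = None
    sufficiency: Sufficiency
    distinct_days: int


class GoalStatusKind(str, Enum):
    at_goal = "at_goal"
    above_goal = "above_goal"


class GoalStatus(BaseModel):
    status: GoalStatusKind
    near_goal_within_margin: bool = False
    safety_floor_flag: bool = False

    @property
    def at_goal(self) -> bool:
        return self.status is GoalStatusKind.at_goal


class MeasurementSlot(BaseModel):
    date: dt.date
    session: str  # "am" | "pm"
    replicate: int  # 1 | 2


class InsufficientDataError(ValueError):
    """Raised when an operation needs at least a minimal week of readings."""


def generate_schedule(window: str, start: dt.date) -> list[MeasurementSlot]:
    """Measurement slots for an ``optimal`` (7-day) or ``minimal`` (3-day) week.

    Each day carries two sessions (morning and evening, before
    medications) of duplicate readings: 4 slots/day.
    """
    days = {"optimal": 7, "minimal": 3}.get(window)
    if days is None:
        raise ValueError(f"window must be 'optimal' or 'minimal', got {window!r}")
    return [
        MeasurementSlot(date=start + dt.timedelta(days=d), session=session, replicate=rep)
        for d in range(days)
        for session in ("am", "pm")
        for rep in (1, 2)
    ]


def _channel_mean(values: list[float], outlier_sd: float) -> tuple[float, int]:
    """Mean after one-pass exclusion of values > ``outlier_sd`` sample-SDs out."""
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    if sd == 0:
        return mean, 0
    survivors = [v for v in values if abs(v - mean) <= outlier_sd * sd]
    if not survivors:  # pathological; keep everything rather than nothing
        return mean, 0
    return sum(survivors) / len(survivors), n - len(survivors)


def weekly_average(
    readings: list[BPReading],
    window_start: dt.date,
    thresholds: Optional[Thresholds] = None,
) -> WeeklyBPSummary:
    """Aggregate one week of home readings into per-channel means.

    Only readings within [window_start, window_start + 7 days) count.
    SBP and DBP are averaged independently, each with its own outlier
    pass; heart rate is averaged without exclusion. Sufficiency reflects
    both the reading count and the number of distinct calendar days.
    """
    t = thresholds or default_config()[0]
    window_end = window_start + dt.timedelta(days=t.alert_window_days)
    in_window = [
        r for r in readings if window_start <= r.timestamp.date() < window_end
    ]
    n = len(in_window)
    days = len({r.timestamp.date() for r in in_window})

    if n >= t.optimal_readings and days >= t.optimal_days:
        sufficiency = Sufficiency.optimal
    elif n >= t.minimal_readings and days >= t.minimal_days:
        sufficiency = Sufficiency.minimal
    else:
        sufficiency = Sufficiency.insufficient

    if n == 0:
        return WeeklyBPSummary(
            window_start=window_start, n_readings=0,
            sufficiency=Sufficiency.insufficient, distinct_days=0,
        )

    mean_sbp, excl_sbp = _channel_mean([float(r.sbp) for r in in_window], t.outlier_sd)
    mean_dbp, excl_dbp = _channel_mean([float(r.dbp) for r in in_window], t.outlier_sd)
    hrs = [float(r.hr) for r in in_window if r.hr is not None]
    mean_hr = sum(hrs) / len(hrs) if hrs else None

    return WeeklyBPSummary(
        window_start=window_start,
        n_readings=n,
        n_excluded_sbp=excl_sbp,
        n_excluded_dbp=excl_dbp,
        mean_sbp=mean_sbp,
        mean_dbp=mean_dbp,
        mean_hr=mean_hr,
        sufficiency=sufficiency,
        distinct_days=days,
    )


def goal_status(
    summary: WeeklyBPSummary,
    frail: bool,
    thresholds: Optional[Thresholds] = None,
) -> GoalStatus:
    """Classify a sufficient weekly summary against the program BP goal.

    Above goal iff mean SBP >= goal SBP or mean DBP >= goal DBP.
    ``near_goal_within_margin`` marks above-goal weeks where every
    channel that is above goal sits less than the chlorthalidone-switch
    margin (10 mmHg) from its goal. The safety floor (mean SBP < 105 or
    DBP < 50) is flagged here; the heart-rate floor for beta-blocker
    patients is the engine's to evaluate.
    """
    if summary.sufficiency is Sufficiency.insufficient:
        raise InsufficientDataError(
            "goal classification requires at least a minimal week of readings"
        )
    t = thresholds or default_config()[0]
    goal_sbp, goal_dbp = t.goal(frail)
    sbp, dbp = summary.mean_sbp, summary.mean_dbp
    above = sbp >= goal_sbp or dbp >= goal_dbp

    near = False
    if above:
        distances = []
        if sbp >= goal_sbp:
            distances.append(sbp - goal_sbp)
        if dbp >= goal_dbp:
            distances.append(dbp - goal_dbp)
        near = all(d < t.chlorthalidone_margin for d in distances)

    floor = sbp < t.safety_floor_sbp or dbp < t.safety_floor_dbp
    return GoalStatus(
        status=GoalStatusKind.above_goal if above else GoalStatusKind.at_goal,
        near_goal_within_margin=near,
        safety_floor_flag=floor,
    )


def classify_transition(
    state: ProgramState,
    summary: WeeklyBPSummary,
    frail: bool,
    any_med_change_yet: bool,
    weeks_since_titration: float,
    thresholds: Optional[Thresholds] = None,
) -> ProgramState:
    """Program-state transition driven by one closed weekly summary.

    At-goal before any medication change means white-coat hypertension or
    effect (maintenance handling, no drug started). At-goal at least
    2 weeks after a titration confirms control and enters maintenance.
    Above goal always (re-)enters active titration. Insufficient weeks,
    and terminal states, leave the state unchanged.
    """
    if state in (ProgramState.referred, ProgramState.withdrawn):
        return state
    if summary.sufficiency is Sufficiency.insufficient:
        logger.warning("insufficient weekly summary: state %s unchanged", state.value)
        return state
    status = goal_status(summary, frail, thresholds)

    if status.at_goal:
        if state is ProgramState.enrolled_baseline and not any_med_change_yet:
            return ProgramState.white_coat
        if state is ProgramState.active_titration:
            # control must hold >= 2 weeks after the titration to confirm
            if weeks_since_titration >= 2:
                return ProgramState.maintenance
            return state
        if state in (ProgramState.maintenance, ProgramState.white_coat):
            return state
        logger.warning("no transition defined for %s at goal; state unchanged", state.value)
        return state
    # above goal
    if state in (
        ProgramState.enrolled_baseline,
        ProgramState.active_titration,
        ProgramState.maintenance,
        ProgramState.white_coat,
    ):
        return ProgramState.active_titration
    return state
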