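"""Shared domain types, the threshold registry, and the dosing table.

Every other module consumes these. All clinical cut-points live in
:class:`Thresholds` and are read from config, never hard-coded in rule
logic; the drug content (agents, dose steps, combination products) lives
in :class:`DosingTable` so it can be edited without code changes.
"""

from __future__ import annotations

import datetime as dt
import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """Raised when a configuration document is missing or malformed."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Sex(str, Enum):
    male = "male"
    female = "female"


class DrugClass(str, Enum):
    """Antihypertensive drug classes used by the program.

    ARB and ACEI are distinct classes but occupy a single RAAS-blocker
    slot in any regimen: a patient is never on both simultaneously.
    """

    CCB = "CCB"
    ARB = "ARB"
    ACEI = "ACEI"
    TD = "TD"
    MRA = "MRA"
    BB = "BB"

    @property
    def is_raas(self) -> bool:
        return self in (DrugClass.ARB, DrugClass.ACEI)


RAAS_CLASSES = frozenset({DrugClass.ARB, DrugClass.ACEI})
#: Classes whose initiation or titration is gated on a recent metabolic panel.
LAB_REQUIRING_CLASSES = frozenset(
    {DrugClass.ARB, DrugClass.ACEI, DrugClass.TD, DrugClass.MRA}
)


class ReadingContext(str, Enum):
    home = "home"
    office = "office"
    standing = "standing"
    seated = "seated"


class LabRole(str, Enum):
    baseline = "baseline"
    followup = "followup"


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

class BPReading(BaseModel):
    """One timestamped blood-pressure measurement (home or office)."""

    model_config = ConfigDict(frozen=True)

    timestamp: dt.datetime
    sbp: int = Field(gt=0)
    dbp: int = Field(gt=0)
    hr: Optional[int] = Field(default=None, gt=0)
    context: ReadingContext = ReadingContext.home

    @model_validator(mode="after")
    def _sbp_above_dbp(self) -> "BPReading":
        if self.sbp <= self.dbp:
            raise ValueError(f"sbp ({self.sbp}) must exceed dbp ({self.dbp})")
        return self

    @property
    def date(self) -> dt.date:
        return self.timestamp.date()


class LabPanel(BaseModel):
    """A basic metabolic panel (plus optional urine albumin/creatinine)."""

    model_config = ConfigDict(frozen=True)

    draw_date: dt.date
    k: float = Field(gt=0, description="potassium, mmol/L")
    na: float = Field(gt=0, description="sodium, mmol/L")
    creatinine: float = Field(gt=0, description="mg/dL")
    egfr: float = Field(gt=0, description="ml/min/1.73 m^2")
    uacr: Optional[float] = Field(
        default=None, ge=0, description="urine microalbumin/creatinine, mg/g Cr"
    )
    role: LabRole = LabRole.followup


class MedicationState(BaseModel):
    """One agent in a patient's regimen, positioned on its dose ladder."""

    agent: str
    dose_step: int = Field(ge=0, description="index into the agent's dose steps")
    start_date: dt.date
    last_change_date: dt.date
    intolerant: bool = False

    def at_max(self, table: "DosingTable") -> bool:
        return self.dose_step >= len(table.agent(self.agent).steps) - 1


class PatientProfile(BaseModel):
    """Demographics, comorbidity and exclusion flags driving pathway choice."""

    patient_id: str
    age: int = Field(ge=0)
    sex: Sex
    weight: float = Field(gt=0, description="lb")
    frail: bool = False
    contraception: bool = False
    diabetes: bool = False
    heart_failure_reduced_EF: bool = False
    severe_aortic_stenosis: bool = False
    bilateral_renal_artery_stenosis: bool = False
    pregnant_or_breastfeeding: bool = False
    orthostatic_hypotension: bool = False
    terminal_condition: bool = False
    can_consent: bool = True
    ascvd_risk_10yr: Optional[float] = Field(default=None, ge=0, le=1)
    medication_naive: bool = True
    current_meds: list[MedicationState] = Field(default_factory=list)
    reactive_airway: bool = False

    @model_validator(mode="after")
    def _contraception_female_only(self) -> "PatientProfile":
        # contraception status is only meaningful for female patients;
        # normalise it away for males rather than rejecting the record
        if self.sex is Sex.male and self.contraception:
            object.__setattr__(self, "contraception", False)
        return self


# ---------------------------------------------------------------------------
# Threshold registry
# ---------------------------------------------------------------------------

class Thresholds(BaseModel):
    """Every numeric cut-point the program rules consume.

    Units: pressures mmHg, electrolytes mmol/L, creatinine mg/dL, eGFR
    ml/min/1.73 m^2, weight lb, heart rate bpm, windows days/weeks/months.
    """

    model_config = ConfigDict(extra="forbid")

    # BP goals
    goal_sbp_standard: float = 130
    goal_dbp_standard: float = 80
    goal_sbp_frail: float = 135
    goal_dbp_frail: float = 85

    # orthostatic hypotension postural drop
    oh_sbp_drop: float = 20
    oh_dbp_drop: float = 10

    # critical-value alerts
    alert_low_sbp: float = 90
    alert_high_dbp: float = 120
    alert_high_sbp: float = 200
    alert_sbp_190: float = 190
    alert_sbp_180: float = 180
    alert_sbp_190_days: int = 2
    alert_sbp_180_days: int = 3
    alert_window_days: int = 7

    # safety floors
    safety_floor_sbp: float = 105
    safety_floor_dbp: float = 50
    hr_floor_bb: float = 55

    # weekly aggregation
    outlier_sd: float = 3
    optimal_readings: int = 28
    optimal_days: int = 7
    minimal_readings: int = 12
    minimal_days: int = 3

    # titration cadence
    titration_lockout_weeks: float = 1
    titration_lockout_weeks_mra: float = 6
    chlorthalidone_margin: float = 10

    # lab gates
    k_max_raas: float = 5.2
    k_warn_raas: float = 4.5
    k_min_td: float = 3.5
    na_min_td: float = 135
    na_warn_td: float = 140
    k_warn_td: float = 4.2
    egfr_min: float = 30
    egfr_raas_pathway: float = 60
    uacr_pathway: float = 30
    creat_rise_pct: float = 30
    k_rise_pct: float = 15
    k_abs_for_rise: float = 5.0
    egfr_drop_pct: float = 30

    # lifestyle / stage-2 band
    lifestyle_trial_months: int = 2
    stage2_sbp: float = 140
    stage2_dbp: float = 90

    # lab scheduling
    post_titration_lab_window_weeks: tuple[float, float] = (1, 2)
    final_lab_window_weeks: float = 4
    baseline_lab_max_age_months: int = 12

    # eligibility
    weight_limit_female: float = 270
    weight_limit_male: float = 290
    age_min: int = 26
    age_min_dm: int = 40
    age_max: int = 80
    age_childbearing: int = 45
    office_recent_months: int = 6
    office_mean_months: int = 18

    # combination-pill stability
    combo_stable_weeks: float = 4

    @model_validator(mode="after")
    def _frail_goals_relax(self) -> "Thresholds":
        if not (self.goal_sbp_frail > self.goal_sbp_standard
                and self.goal_dbp_frail > self.goal_dbp_standard):
            raise ValueError("frail goals must be strictly greater than standard goals")
        if self.post_titration_lab_window_weeks[0] > self.post_titration_lab_window_weeks[1]:
            raise ValueError("post_titration_lab_window_weeks must be (earliest, latest)")
        return self

    def goal(self, frail: bool) -> tuple[float, float]:
        """(SBP goal, DBP goal) for a patient's frailty status."""
        if frail:
            return self.goal_sbp_frail, self.goal_dbp_frail
        return self.goal_sbp_standard, self.goal_dbp_standard


# ---------------------------------------------------------------------------
# Dosing table
# ---------------------------------------------------------------------------

class DoseStep(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    mg: float = Field(gt=0)


class AgentEntry(BaseModel):
    """One agent's dose ladder and prescribing attributes."""

    name: str
    drug_class: DrugClass
    steps: list[DoseStep] = Field(min_length=1)
    standard_start_step: int = 0
    conservative_start_step: Optional[int] = None
    once_daily: bool = True
    avoid: bool = False  # listed for recognition/switching only, never started

    @model_validator(mode="after")
    def _validate(self) -> "AgentEntry":
        mgs = [s.mg for s in self.steps]
        if any(b <= a for a, b in zip(mgs, mgs[1:])):
            raise ValueError(f"{self.name}: dose steps must be strictly increasing in mg")
        if not 0 <= self.standard_start_step < len(self.steps):
            raise ValueError(f"{self.name}: standard_start_step out of range")
        if self.conservative_start_step is None:
            # conservative dosing = one step below the standard start, floored
            object.__setattr__(
                self, "conservative_start_step", max(self.standard_start_step - 1, 0)
            )
        if self.conservative_start_step > self.standard_start_step:
            raise ValueError(
                f"{self.name}: conservative starting step must not exceed standard"
            )
        return self

    @property
    def requires_labs(self) -> bool:
        return self.drug_class in LAB_REQUIRING_CLASSES

    @property
    def max_step(self) -> int:
        return len(self.steps) - 1


class ComboProduct(BaseModel):
    model_config = ConfigDict(frozen=True)

    components: tuple[str, str]  # (RAAS agent, TD agent)
    product: str


class DosingTable(BaseModel):
    agents: list[AgentEntry]
    combinations: list[ComboProduct] = Field(default_factory=list)
    default_arb: str = "irbesartan"

    @model_validator(mode="after")
    def _validate(self) -> "DosingTable":
        names = [a.name for a in self.agents]
        if len(set(names)) != len(names):
            raise ValueError("duplicate agent names in dosing table")
        by_name = {a.name: a for a in self.agents}
        if self.default_arb not in by_name:
            raise ValueError(f"default_arb {self.default_arb!r} not in table")
        if by_name[self.default_arb].drug_class is not DrugClass.ARB:
            raise ValueError("default_arb must be an ARB")
        for combo in self.combinations:
            for name in combo.components:
                if name not in by_name:
                    raise ValueError(f"combination references unknown agent {name!r}")
        return self

    def agent(self, name: str) -> AgentEntry:
        for a in self.agents:
            if a.name == name:
                return a
        raise KeyError(f"unknown agent {name!r}")

    def has_agent(self, name: str) -> bool:
        return any(a.name == name for a in self.agents)

    def agents_of_class(self, cls: DrugClass) -> list[AgentEntry]:
        return [a for a in self.agents if a.drug_class is cls]

    def combo_for(self, raas: str, td: str) -> Optional[ComboProduct]:
        for c in self.combinations:
            if c.components == (raas, td):
                return c
        return None


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG_RESOURCE = "default_config.yaml"


def _config_text() -> str:
    return (resources.files("htn_rms") / "data" / _DEFAULT_CONFIG_RESOURCE).read_text()


def load_config(path: Union[str, Path, None] = None) -> tuple[Thresholds, DosingTable]:
    """Load and validate the thresholds registry and dosing table.

    With ``path=None`` the packaged default config is used. The document
    must carry ``thresholds:`` and ``dosing_table:`` sections; every
    threshold key is required (no silent fallback to code defaults when
    loading an explicit file).
    """
    if path is None:
        raw = yaml.safe_load(_config_text())
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text())

    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    for section in ("thresholds", "dosing_table"):
        if section not in raw:
            raise ConfigError(f"config missing required section: {section}")

    declared = set(raw["thresholds"])
    required = set(Thresholds.model_fields)
    missing = required - declared
    if missing:
        raise ConfigError(
            "config missing threshold key(s): " + ", ".join(sorted(missing))
        )
    try:
        thresholds = Thresholds.model_validate(raw["thresholds"])
    except ValidationError as exc:
        raise ConfigError(f"invalid thresholds: {exc}") from exc
    try:
        table = DosingTable.model_validate(raw["dosing_table"])
    except ValidationError as exc:
        raise ConfigError(f"invalid dosing_table: {exc}") from exc
    return thresholds, table


def dump_config(thresholds: Thresholds, table: DosingTable, path: Union[str, Path]) -> None:
    """Serialize a config document that :func:`load_config` round-trips."""
    doc = {
        "thresholds": json.loads(thresholds.model_dump_json()),
        "dosing_table": json.loads(table.model_dump_json()),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_config() -> tuple[Thresholds, DosingTable]:
    """The shipped default thresholds and dosing table."""
    return load_config(None)
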