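# htn-rms

A deterministic, config-driven decision engine for **remote hypertension
management**: the clinical algorithm of a pharmacist-run home
blood-pressure telemonitoring program operating under a collaborative
drug therapy management (CDTM) agreement, implemented end to end as a
testable Python package — eligibility screening, weekly home-BP
aggregation, critical-value alerting, lab-gated prescribing, a
medication-titration pathway engine, and a synthetic-cohort simulator
that closes the loop.

It is written for digital-health engineers and clinical informaticists
who need the *rules* of such a program as executable, auditable code:
every threshold is configuration, every decision carries
machine-readable rationale codes, and the whole loop runs offline on
synthetic patients.

## The algorithm

Patients transmit scheduled home readings (two sessions/day of
duplicate measurements; 7 days/28 readings is an optimal week,
3 days/12 minimal). Each week, per channel,

> mean over readings after removing values more than 3 sample SD from
> the channel mean (one pass),

is compared with the program goal — SBP < 130 and DBP < 80 mmHg, or
< 135/85 with frailty. At goal before any drug change ⇒ white-coat
hypertension, maintenance without medication; at goal ≥ 2 weeks after a
titration ⇒ controlled, maintenance. Above goal, the engine emits
exactly one action per review, in priority order: safety floors
(SBP < 105, DBP < 50, HR < 55 on a beta blocker ⇒ physician
conversation), titration lockout (1 week; 6 weeks for MRA), a 2-month
lifestyle trial for medication-naive stage-1 BP with 10-year ASCVD risk
< 10%, then pathway escalation:

* **Standard pathway** — CCB → ARB/ACEI → thiazide;
* **RAAS-first pathway** (diabetes, eGFR < 60, or UACR ≥ 30 mg/g) —
  ARB/ACEI → CCB → thiazide;
* **Childbearing potential** (women < 45 without contraception) —
  CCB → labetalol;

always maximize-before-add, chlorthalidone as the thiazide up-titration
when every above-goal channel is < 10 mmHg from goal, then a
secondary-cause screen, then MRA (if K ≤ 4.5 plainly; conservative dose
to K < 5.2) or beta blocker (HR ≥ 55), then specialist referral.
ARB/ACEI, thiazide, and MRA steps are gated on a recent metabolic
panel (e.g. ARB blocks at K ≥ 5.2, eGFR < 30, or an eGFR fall ≥ 30%
from baseline). Daily alert scanning flags SBP ≤ 90, DBP ≥ 120,
SBP ≥ 200 on any one day, and 2 days of SBP ≥ 190 or 3 days of
SBP ≥ 180 in a rolling 7-day window. A COVID risk-mitigation mode
substitutes lab-free classes (CCB, then labetalol) when laboratories
are unreachable.

All cut-points live in one YAML config (`thresholds:` +
`dosing_table:`); see `docs/methods.md` for the full rule set and the
simulator's response model.

## Worked example

One above-goal week for a medication-naive 58-year-old man with normal
labs:

```bash
htn-rms recommend --profile profile.json --bp bp.csv \
    --labs labs.csv --as-of 2022-06-06
```

```json
{
  "patient_id": "pt-0042",
  "window_start": "2022-05-30",
  "n_readings": 28,
  "distinct_days": 7,
  "n_excluded_sbp": 0,
  "n_excluded_dbp": 0,
  "mean_sbp": 152.0,
  "mean_dbp": 95.0,
  "mean_hr": 72.0,
  "sufficiency": "optimal",
  "lab_warnings": [],
  "goal_status": "above_goal",
  "safety_floor_flag": false,
  "recommendation": {
    "action": "START",
    "agent": "amlodipine",
    "target_dose_step": 1,
    "rationale_codes": ["PATHWAY_NEXT_LINE"],
    "requires_lab_gate": false
  }
}
```

Reading it: 28 readings on 7 distinct days (an optimal week, nothing
excluded as an outlier), weekly mean 152/95 mmHg is above the 130/80
goal, no safety floor is breached, and the first line of the standard
pathway is a dihydropyridine CCB — start amlodipine at its standard
starting step (index 1 = 5 mg daily), no lab gate needed for a CCB.

Other commands: `screen` (eligibility, exit 3 when ineligible),
`weekly-report`, `alerts` (JSON-lines alert events), `lab-gate`,
`simulate` (closed-loop synthetic cohort; `--seed` reproducible). The
same operations are importable from `htn_rms` as plain functions.

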