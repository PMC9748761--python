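# Methods

`htn-rms` is a deterministic implementation of a remote hypertension
management protocol of the kind run by pharmacist-led telemonitoring
programs under collaborative drug therapy management (CDTM): patients
transmit scheduled home blood-pressure readings, a weekly report is
aggregated and classified against a goal, and a rule engine issues at
most one medication action per review, gated on laboratory safety rules.
This note records the model, the defaults, and the design choices made
where the protocol text left the design open.

## The clinical rule set

**Goals.** Control is weekly mean SBP < 130 and DBP < 80 mmHg; frailty
(assistive-device use or confirmed non-mechanical falls within
12 months) relaxes the goal to < 135/85. A weekly mean at goal before
any medication change is classified as white-coat hypertension/effect
and the patient enters maintenance without drug therapy; at goal at
least 2 weeks after a titration confirms control.

**Weekly aggregation.** The monitoring schedule is two sessions/day
(morning and evening, before medications) of duplicate seated readings:
7 days/28 readings is the optimal week, 3 days/12 readings the minimal
acceptable one; the minimal grade additionally requires 3 distinct
calendar days. SBP and DBP are averaged independently; values more than
3 sample standard deviations (n−1 denominator) from the channel mean
are removed in a single pass and the mean recomputed over survivors. An
outlying systolic value therefore does not discard its paired diastolic
value. The SD is the week's own (no longer-run variance estimate is
kept), heart rate is averaged without an outlier pass, and iterated
trimming is not performed — each of these was an open choice and the
simplest reading was taken.

**Eligibility.** Inclusion fires on the single most recent office
reading (≥ 135/85, within 6 months) or on the channel-wise mean of the
three most recent readings within 18 months crossing the same cut-offs
(either channel suffices). Older readings never satisfy the
"most recent" rule. Exclusions: age < 26 (< 40 with diabetes) or > 80,
pregnancy/breastfeeding, HFrEF, severe aortic stenosis, bilateral renal
artery stenosis, eGFR < 30, orthostatic hypotension (problem-list flag
or a postural test: seated-to-standing drop ≥ 20 systolic or
≥ 10 diastolic, boundaries inclusive per the standard OH definition),
terminal condition, inability to consent, cuff weight limits (women
> 270 lb, men > 290 lb), and a controlled 24-h ABPM (< 130/80) within
the past year. The office-BP file is assumed pre-filtered to regular
clinic visits.

**Alerts.** Single-day rules (any reading: SBP ≤ 90, DBP ≥ 120,
SBP ≥ 200) and rolling 7-day rules (2 distinct days of SBP ≥ 190,
3 distinct days of SBP ≥ 180). A "day" is the local calendar date; one
crossing reading qualifies the day, and repeats on the same date count
once. A 200-mmHg reading also feeds the 190/180 day counts. Events are
deduplicated per (type, window); SBP ≥ 200 without alarm symptoms and
SBP ≤ 90 with dizziness earn a 1-hour recheck, persistence means call
the program, and everything else is clinician-triaged. Any alarm
symptom (chest pain, acute dyspnoea, severe headache, oropharyngeal
swelling, unclear thinking, visual changes, nausea/vomiting) means call
EMS with immediate clinical-lead notification.

**Pathways and titration.** First line is a dihydropyridine CCB
(standard pathway) or an ARB/ACEI (diabetes, eGFR < 60, or urine
microalbumin/Cr ≥ 30 mg/g). Women of childbearing potential (< 45, no
contraception) go CCB then labetalol; this rule outranks the RAAS
indications, since the RAAS pathway is defined only for patients not of
childbearing potential. A missing urine albumin/Cr is treated as below
the cut-off with a logged caveat. Escalation is strictly
maximize-before-add; new RAAS starts use the program-default potent ARB
(irbesartan here; losartan and non-lisinopril ACEIs are switched to it,
lisinopril is titrated in place). The thiazide is third line unless
contraindicated (hyponatremia); at maximum hydrochlorothiazide with
every above-goal channel < 10 mmHg from goal, chlorthalidone is the TD
up-titration (a switch). Uncontrolled on a maximal conventional
three-drug regimen (max-dose or documented-intolerant CCB + RAAS + TD)
triggers the secondary-cause screen (renin, aldosterone, potassium,
metanephrines); positivity is a clinician-lead judgement supplied as a
boolean. A negative screen opens the fourth line: MRA if potassium
permits (eplerenone for men, spironolactone otherwise), else a beta
blocker (metoprolol with reactive airway, labetalol otherwise), never
below 55 bpm. Exhaustion refers to the hypertension specialist.

Safety interlocks, in priority order before any dosing step: at goal →
hold; weekly mean SBP < 105, DBP < 50, or HR < 55 on a beta blocker →
physician conversation; a dose change within the last week (6 weeks for
an MRA) → hold; medication-naive stage-1 BP (< 140/90) with 10-year
ASCVD risk < 10% → a 2-month lifestyle trial before any drug.

**Lab gates.** CCB/BB are lab-free. ARB/ACEI block at K ≥ 5.2, eGFR
< 30, or an eGFR fall ≥ 30% from the enrolment baseline; TD at K < 3.5,
Na < 135, or eGFR < 30; MRA combines both sets and passes at the
conservative dose for 4.5 < K < 5.2 (with a clinical-lead discussion
code). Comparisons use the printed strict/inclusive forms verbatim. The
program-level warning for a K rise uses "> 15%" (strict) while the
per-class repeat-labs rule uses "≥ 15%" — the source prints them
differently and each is implemented as printed in its own rule. The
repeat-labs trigger (creatinine rise ≥ 30%; K rise ≥ 15% conjoined with
K > 5.0 for RAAS/MRA; K < 3.5 or Na < 135 for TD) is ordered
two-step: repeat first, down-titrate one step only once a repeat draw
has confirmed. Panels are drawn 1–2 weeks after initiation and after
titrations, every other titration when the ladder has ≥ 3 steps and
previous values were normal, and always within 4 weeks of the final
dose. A baseline panel older than 12 months is unusable (configurable).

**COVID risk-mitigation mode.** When the next step would need labs and
labs are unreachable: at ≥ 140/90 the step is substituted with a
lab-free class (CCB first, labetalol once the CCB is maxed, still
subject to the heart-rate floor); below 140/90 a 2-month lifestyle
trial defers drug changes. With labs merely constrained, new starts use
conservative dosing. Conservative dosing is modelled as one step below
the standard starting step (floored at step 0); the source names the
strategy but not the doses. Frail patients also start conservatively.

## Configuration

Every numeric cut-point lives in the `thresholds:` section of one YAML
document and is resolved through the registry at call time — a test
changes a goal in config and observes the classification boundary move.
The dose ladders live in `dosing_table:`. The published step sequences
(irbesartan 75/150/300 mg; HCTZ 12.5/25 mg with chlorthalidone 25 mg as
the TD up-titration; spironolactone 12.5/25/50 mg) are shipped
verbatim; the remaining agents carry editorial placeholder ladders from
common practice, marked as replaceable site content. Validation is done
with pydantic models; `docs/config.schema.json` is generated from them.

## The synthetic cohort

The protocol publishes no patient response model, so the simulator
supplies the statistical structure the engine's inputs must have — it
is a test harness for the rules, not an epidemiological model.

* Baseline true home BP: SBP ~ N(150, 12), DBP ~ N(92, 8) mmHg — an
  uncontrolled newly-referred cohort.
* Dose response: linear-additive, ~5 mmHg SBP per dose step for
  first-line classes (4 for TD/MRA/BB), DBP at half the SBP drop,
  scaled by a patient-level lognormal sensitivity (σ = 0.3). Step
  index 0 counts as one dose unit. The linearity is what lets the
  titration count be inverted in closed form for the noise-free
  recovery test.
* Measurement: home readings are true BP + N(0, 8) noise; office
  readings add a white-coat offset ~ N(10, 6) (offset on office
  readings only, which is what produces white-coat classifications).
  Adherence thins the 28-slot schedule at 0.9 per slot.
* Labs: RAAS exposure raises K (+0.10/step) and creatinine (+4%/step)
  and lowers eGFR; TD lowers K and Na; MRA raises K (+0.20/step); all
  with draw noise.
* Comorbidity mix: frailty 15%, diabetes 25%, CKD (eGFR 35–59) 15%,
  childbearing potential 10% of women, reactive airway 10%.

Each patient gets an independent pseudo-random stream
(master seed + patient index), so editing the cohort never perturbs
other patients' trajectories; the whole simulation log is
bit-reproducible for a given seed. Applied recommendations take effect
at the start of the next simulated week. What the simulator does *not*
model — pharmacokinetics, tolerance developing over time, adverse
events beyond lab shifts, dropout, device failure — bounds what passing
simulation tests show: they certify the decision logic against the
stated rules, not clinical outcomes in real cohorts.

## Numerical and degenerate-input choices

* A constant week has SD 0: nothing is excluded (no 0/0 z-scores).
* If exclusion would remove every value, nothing is excluded.
* An empty week returns an `insufficient` summary with undefined means
  rather than raising; goal classification refuses insufficient weeks.
* Tied office-visit dates are broken by record order with a warning.
* Week boundaries are local calendar dates; all dates ISO-8601.
* The "2 weeks after titration" maintenance check is evaluated when the
  qualifying weekly summary closes.
* Test and demonstration problem sizes: cohorts of 12–60 patients over
  16–40 weeks, 10,000 randomized engine invocations for the safety
  fuzz, and exhaustive 128-pattern enumeration for the alert scanner —
  chosen so the whole suite illustrates the full loop in seconds.

## Known limitations

* The engine emits one action per invocation; batching multiple
  simultaneous changes is out of scope.
* Drug-interaction checking beyond the stated rules, formulary/cost
  logic, e-prescribing, and notification delivery are not modelled.
* Intolerance is an input flag, never inferred from data.
* The placeholder dose ladders and conservative-dose convention are
  editorial; sites replace them in config.
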