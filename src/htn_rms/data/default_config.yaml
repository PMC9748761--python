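# Default program configuration: threshold registry + dosing table.
#
# Dose ladders for irbesartan, hydrochlorothiazide/chlorthalidone and
# spironolactone follow the program's published step sequences; the
# remaining agents carry editorial placeholder ladders chosen from common
# prescribing practice and are meant to be replaced by a site's own
# formulary without code changes.

thresholds:
  goal_sbp_standard: 130
  goal_dbp_standard: 80
  goal_sbp_frail: 135
  goal_dbp_frail: 85
  oh_sbp_drop: 20
  oh_dbp_drop: 10
  alert_low_sbp: 90
  alert_high_dbp: 120
  alert_high_sbp: 200
  alert_sbp_190: 190
  alert_sbp_180: 180
  alert_sbp_190_days: 2
  alert_sbp_180_days: 3
  alert_window_days: 7
  safety_floor_sbp: 105
  safety_floor_dbp: 50
  hr_floor_bb: 55
  outlier_sd: 3
  optimal_readings: 28
  optimal_days: 7
  minimal_readings: 12
  minimal_days: 3
  titration_lockout_weeks: 1
  titration_lockout_weeks_mra: 6
  chlorthalidone_margin: 10
  k_max_raas: 5.2
  k_warn_raas: 4.5
  k_min_td: 3.5
  na_min_td: 135
  na_warn_td: 140
  k_warn_td: 4.2
  egfr_min: 30
  egfr_raas_pathway: 60
  uacr_pathway: 30
  creat_rise_pct: 30
  k_rise_pct: 15
  k_abs_for_rise: 5.0
  egfr_drop_pct: 30
  lifestyle_trial_months: 2
  stage2_sbp: 140
  stage2_dbp: 90
  post_titration_lab_window_weeks: [1, 2]
  final_lab_window_weeks: 4
  baseline_lab_max_age_months: 12
  weight_limit_female: 270
  weight_limit_male: 290
  age_min: 26
  age_min_dm: 40
  age_max: 80
  age_childbearing: 45
  office_recent_months: 6
  office_mean_months: 18
  combo_stable_weeks: 4

dosing_table:
  default_arb: irbesartan
  agents:
    - name: amlodipine
      drug_class: CCB
      standard_start_step: 1
      steps:
        - {label: "2.5 mg daily", mg: 2.5}
        - {label: "5 mg daily", mg: 5}
        - {label: "10 mg daily", mg: 10}
    - name: irbesartan
      drug_class: ARB
      standard_start_step: 0
      steps:
        - {label: "75 mg daily", mg: 75}
        - {label: "150 mg daily", mg: 150}
        - {label: "300 mg daily", mg: 300}
    - name: valsartan
      drug_class: ARB
      standard_start_step: 0
      steps:
        - {label: "80 mg daily", mg: 80}
        - {label: "160 mg daily", mg: 160}
        - {label: "320 mg daily", mg: 320}
    - name: losartan
      drug_class: ARB
      avoid: true          # recognised for switching only, never started
      standard_start_step: 0
      steps:
        - {label: "25 mg daily", mg: 25}
        - {label: "50 mg daily", mg: 50}
        - {label: "100 mg daily", mg: 100}
    - name: lisinopril
      drug_class: ACEI
      standard_start_step: 0
      steps:
        - {label: "10 mg daily", mg: 10}
        - {label: "20 mg daily", mg: 20}
        - {label: "40 mg daily", mg: 40}
    - name: hydrochlorothiazide
      drug_class: TD
      standard_start_step: 0
      steps:
        - {label: "12.5 mg daily", mg: 12.5}
        - {label: "25 mg daily", mg: 25}
    - name: chlorthalidone
      drug_class: TD
      standard_start_step: 0
      steps:
        - {label: "25 mg daily", mg: 25}
    - name: spironolactone
      drug_class: MRA
      standard_start_step: 0
      steps:
        - {label: "12.5 mg daily", mg: 12.5}
        - {label: "25 mg daily", mg: 25}
        - {label: "50 mg daily", mg: 50}
    - name: eplerenone
      drug_class: MRA
      standard_start_step: 0
      steps:
        - {label: "25 mg daily", mg: 25}
        - {label: "50 mg daily", mg: 50}
    - name: labetalol
      drug_class: BB
      once_daily: false
      standard_start_step: 0
      steps:
        - {label: "100 mg twice daily", mg: 200}
        - {label: "200 mg twice daily", mg: 400}
        - {label: "300 mg twice daily", mg: 600}
    - name: metoprolol
      drug_class: BB
      standard_start_step: 0
      steps:
        - {label: "succinate 25 mg daily", mg: 25}
        - {label: "succinate 50 mg daily", mg: 50}
        - {label: "succinate 100 mg daily", mg: 100}
        - {label: "succinate 200 mg daily", mg: 200}
  combinations:
    - components: [irbesartan, hydrochlorothiazide]
      product: irbesartan/HCTZ
    - components: [valsartan, hydrochlorothiazide]
      product: valsartan/HCTZ
    - components: [losartan, hydrochlorothiazide]
      product: losartan/HCTZ
    - components: [lisinopril, hydrochlorothiazide]
      product: lisinopril/HCTZ
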