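# Default Life's Essential 8 component point schedules (AHA gradations).
# Each component maps a raw clinical/behavioural measurement to 0-100 points,
# with 100 at the guideline-optimal level. Bands are half-open intervals
# [lo, hi) unless noted. All tables are plain data so that alternative
# operationalizations (e.g., cohort-specific diet quantiles) can be swapped
# in without code changes.

diet:
  # DASH-style adherence quantile (1 = lowest adherence), mapped linearly to
  # 0-100 across quantiles: points = (q - 1) / (n_quantiles - 1) * 100.
  n_quantiles: 10

physical_activity:
  # [minimum minutes of moderate-to-vigorous activity per week, points]
  bands:
    - [150, 100]
    - [120, 90]
    - [90, 80]
    - [60, 60]
    - [30, 40]
    - [0.0001, 20]   # any reported activity below 30 min
    - [0, 0]

nicotine:
  # smoking_status codes: 0 never, 1 former quit >=5 y, 2 former quit 1-<5 y,
  # 3 former quit <1 y, 4 current smoker
  status_points: [100, 75, 50, 25, 0]
  secondhand_deduction: 20   # living with an indoor smoker; floor at 0

sleep:
  # [lo hours, hi hours, points]; 7-<9 h is optimal
  bands:
    - [7, 9, 100]
    - [9, 10, 90]
    - [6, 7, 70]
    - [5, 6, 40]
    - [10, 25, 40]
    - [4, 5, 20]
    - [0, 4, 0]

bmi:
  # kg/m^2
  bands:
    - [0, 25, 100]
    - [25, 30, 70]
    - [30, 35, 30]
    - [35, 40, 15]
    - [40, 1000, 0]

lipids:
  # non-HDL cholesterol, mg/dL
  bands:
    - [0, 130, 100]
    - [130, 160, 60]
    - [160, 190, 40]
    - [190, 220, 20]
    - [220, 10000, 0]
  treatment_deduction: 20   # drug-treated lipid levels; floor at 0

glucose:
  # fasting blood glucose, mg/dL. Without diagnosed diabetes the schedule is
  # glucose-based; with diabetes the HbA1c schedule is applied via
  # estimated-average-glucose equivalents (eAG = 28.7*A1c - 46.7).
  no_diabetes_bands:
    - [0, 100, 100]
    - [100, 126, 60]
    - [126, 10000, 40]
  diabetes_bands:
    - [0, 154, 40]      # HbA1c < 7%
    - [154, 183, 30]    # 7-7.9%
    - [183, 212, 20]    # 8-8.9%
    - [212, 240, 10]    # 9-9.9%
    - [240, 10000, 0]   # >= 10%

blood_pressure:
  # Category = worse of the systolic and diastolic categories.
  # sbp_cuts partition SBP into categories 0..4; dbp_cuts into the categories
  # listed in dbp_cats (diastolic has no "elevated" tier).
  sbp_cuts: [120, 130, 140, 160]
  dbp_cuts: [80, 90, 100]
  dbp_cats: [0, 2, 3, 4]
  category_points: [100, 75, 50, 25, 0]
  treatment_deduction: 20   # antihypertensive medication; floor at 0
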