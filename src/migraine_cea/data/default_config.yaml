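horizon:
  n_cycles: 2
  cycle_length_years: 0.25
discount_rate: 0.03
wtp_thresholds:
- 32327.0
- 96981.0
band_values:
- 1.5
- 6.5
- 12.0
- 17.0
- 21.5
- 26.0
initial_distribution: derive-from-cohort
trials:
- name: PROMISE-1
  baseline_mmd_mean: 10.0
  mmd_low: 4.0
  mmd_high: 28.0
  concentration: 10.0
  female_prop: 0.78
  age_mean: 40.0
  age_sd: 11.0
  weight: 0.3333333333333333
- name: PROMISE-2
  baseline_mmd_mean: 20.4
  mmd_low: 4.0
  mmd_high: 28.0
  concentration: 10.0
  female_prop: 0.78
  age_mean: 41.0
  age_sd: 11.0
  weight: 0.3333333333333333
- name: DELIVER
  baseline_mmd_mean: 14.5
  mmd_low: 4.0
  mmd_high: 28.0
  concentration: 10.0
  female_prop: 0.78
  age_mean: 44.6
  age_sd: 11.0
  weight: 0.3333333333333333
strategies:
- name: eptinezumab
  drug_active: true
  transitions:
    orientation: column-major
    table:
      0-3:
      - 1.0
      - 0.56
      - 0.05
      - 0.01
      - 0.0
      - 0.0
      4-9:
      - 0.0
      - 0.44
      - 0.74
      - 0.28
      - 0.04
      - 0.0
      10-14:
      - 0.0
      - 0.0
      - 0.21
      - 0.61
      - 0.4
      - 0.08
      15-19:
      - 0.0
      - 0.0
      - 0.0
      - 0.09
      - 0.53
      - 0.48
      20-24:
      - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.03
      - 0.36
      24+:
      - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.09
  utilities:
    0-3:
      mean: 0.778
      sd: 0.01
    4-9:
      mean: 0.732
      sd: 0.015
    10-14:
      mean: 0.681
      sd: 0.012
    15-19:
      mean: 0.635
      sd: 0.013
    20-24:
      mean: 0.595
      sd: 0.01
    24+:
      mean: 0.553
      sd: 0.012
  costs:
    drug_cost_per_dose: 1708.0
    drug_cost_low: 1366.4
    drug_cost_high: 2049.6
    doses_per_cycle: 1
    admin_cost_per_infusion: 150.0
    cm_acute:
      mean: 270.0
      sd: 135.0
    cm_prevention:
      mean: 37.0
      sd: 18.5
    em_acute:
      mean: 184.0
      sd: 92.0
    em_prevention:
      mean: 27.4
      sd: 13.7
    entry_items:
    - name: mri
      mean: 195.9
      sd: 97.95
      use_prob: 0.9
    - name: ct
      mean: 114.5
      sd: 57.25
      use_prob: 0.5
    - name: ecg
      mean: 4.5
      sd: 2.25
      use_prob: 0.8
    - name: skull_xray
      mean: 6.0
      sd: 3.0
      use_prob: 0.5
    - name: blood_test
      mean: 6.0
      sd: 3.0
      use_prob: 0.9
    - name: botulinum_toxin
      mean: 110.4
      sd: 55.2
      use_prob: 0.5
    - name: tens
      mean: 9.6
      sd: 4.8
      use_prob: 0.3
    - name: occipital_nerve_block
      mean: 0.7
      sd: 0.4
      use_prob: 0.5
- name: placebo
  drug_active: false
  transitions:
    orientation: column-major
    table:
      0-3:
      - 1.0
      - 0.29
      - 0.01
      - 0.0
      - 0.0
      - 0.0
      4-9:
      - 0.0
      - 0.71
      - 0.53
      - 0.08
      - 0.0
      - 0.0
      10-14:
      - 0.0
      - 0.0
      - 0.46
      - 0.61
      - 0.16
      - 0.01
      15-19:
      - 0.0
      - 0.0
      - 0.0
      - 0.31
      - 0.64
      - 0.27
      20-24:
      - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.2
      - 0.5
      24+:
      - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.22
  utilities:
    0-3:
      mean: 0.707
      sd: 0.01
    4-9:
      mean: 0.661
      sd: 0.015
    10-14:
      mean: 0.611
      sd: 0.013
    15-19:
      mean: 0.565
      sd: 0.012
    20-24:
      mean: 0.524
      sd: 0.01
    24+:
      mean: 0.483
      sd: 0.013
  costs:
    drug_cost_per_dose: 0.0
    drug_cost_low: 0.0
    drug_cost_high: 0.0
    doses_per_cycle: 1
    admin_cost_per_infusion: 150.0
    cm_acute:
      mean: 270.0
      sd: 135.0
    cm_prevention:
      mean: 37.0
      sd: 18.5
    em_acute:
      mean: 184.0
      sd: 92.0
    em_prevention:
      mean: 27.4
      sd: 13.7
    entry_items:
    - name: mri
      mean: 195.9
      sd: 97.95
      use_prob: 0.9
    - name: ct
      mean: 114.5
      sd: 57.25
      use_prob: 0.5
    - name: ecg
      mean: 4.5
      sd: 2.25
      use_prob: 0.8
    - name: skull_xray
      mean: 6.0
      sd: 3.0
      use_prob: 0.5
    - name: blood_test
      mean: 6.0
      sd: 3.0
      use_prob: 0.9
    - name: botulinum_toxin
      mean: 110.4
      sd: 55.2
      use_prob: 0.5
    - name: tens
      mean: 9.6
      sd: 4.8
      use_prob: 0.3
    - name: occipital_nerve_block
      mean: 0.7
      sd: 0.4
      use_prob: 0.5
owsa:
  utility_multiplier: 0.1
  transition_multiplier: 0.1
  cost_multiplier: 0.2
psa:
  n: 10000
  seed: 1
  transition_concentration: 100.0
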