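schema_version: 1
settings:
  cycle_length_days: 28
  n_cycles: 195
  annual_discount_rate_costs: 0.05
  annual_discount_rate_outcomes: 0.05
  days_per_year: 365.25
  half_cycle_correction: false
  currency_year: 2021
  inflation_rate: 0.051
  usd_zar_rate: 14.67
unit_costs:
  cost_inpatient_day: 4515.8
  cost_outpatient_nic: 800.0
  cost_outpatient_ic: 2837.0
  price_dex_40mg: 6.28
  price_len_25mg: 1340.03
  price_bort_per_mg: 865.47
utilisation:
  DEX:
    inpatient_days_per_cycle: 0.02
    outpatient_visits_per_cycle: 0.3875
    outpatient_visit_type: NIC
  BORT:
    inpatient_days_per_cycle: 0.0158
    outpatient_visits_per_cycle: 0.5025
    outpatient_visit_type: IC
  LEN/DEX:
    inpatient_days_per_cycle: 0.0125
    outpatient_visits_per_cycle: 0.3325
    outpatient_visit_type: NIC
drug_schedules:
  DEX:
    tiers:
    - first_cycle: 1
      last_cycle: 4
      components:
      - drug: DEX
        units_per_cycle: 12
        price_field: price_dex_40mg
    - first_cycle: 5
      last_cycle: null
      components:
      - drug: DEX
        units_per_cycle: 4
        price_field: price_dex_40mg
  BORT:
    tiers:
    - first_cycle: 1
      last_cycle: 8
      components:
      - drug: BORT
        units_per_cycle: 13.5
        price_field: price_bort_per_mg
    - first_cycle: 9
      last_cycle: null
      components:
      - drug: BORT
        units_per_cycle: 9.0
        price_field: price_bort_per_mg
  LEN/DEX:
    tiers:
    - first_cycle: 1
      last_cycle: 4
      components:
      - drug: LEN
        units_per_cycle: 21
        price_field: price_len_25mg
      - drug: DEX
        units_per_cycle: 12
        price_field: price_dex_40mg
    - first_cycle: 5
      last_cycle: null
      components:
      - drug: LEN
        units_per_cycle: 21
        price_field: price_len_25mg
      - drug: DEX
        units_per_cycle: 4
        price_field: price_dex_40mg
transition_schedules:
  DEX:
    segments:
    - first_cycle: 1
      last_cycle: 6
      matrix:
      - - 0.7920792079207921
        - 0.18811881188118812
        - 0.019801980198019802
      - - 0.0
        - 0.88
        - 0.12
      - - 0.0
        - 0.0
        - 1.0
    - first_cycle: 7
      last_cycle: 26
      matrix:
      - - 0.86
        - 0.14
        - 0.0
      - - 0.0
        - 0.95
        - 0.05
      - - 0.0
        - 0.0
        - 1.0
    - first_cycle: 27
      last_cycle: null
      matrix:
      - - 0.92
        - 0.08
        - 0.0
      - - 0.0
        - 0.94
        - 0.06
      - - 0.0
        - 0.0
        - 1.0
  BORT:
    segments:
    - first_cycle: 1
      last_cycle: 6
      matrix:
      - - 0.888888888888889
        - 0.10101010101010102
        - 0.010101010101010102
      - - 0.0
        - 0.9
        - 0.1
      - - 0.0
        - 0.0
        - 1.0
    - first_cycle: 7
      last_cycle: 26
      matrix:
      - - 0.92
        - 0.08
        - 0.0
      - - 0.0
        - 0.96
        - 0.04
      - - 0.0
        - 0.0
        - 1.0
    - first_cycle: 27
      last_cycle: null
      matrix:
      - - 0.96
        - 0.04
        - 0.0
      - - 0.0
        - 0.95
        - 0.05
      - - 0.0
        - 0.0
        - 1.0
  LEN/DEX:
    segments:
    - first_cycle: 1
      last_cycle: 6
      matrix:
      - - 0.92
        - 0.07
        - 0.01
      - - 0.0
        - 0.9108910891089109
        - 0.0891089108910891
      - - 0.0
        - 0.0
        - 1.0
    - first_cycle: 7
      last_cycle: 26
      matrix:
      - - 0.95
        - 0.05
        - 0.0
      - - 0.0
        - 0.97
        - 0.03
      - - 0.0
        - 0.0
        - 1.0
    - first_cycle: 27
      last_cycle: null
      matrix:
      - - 0.97
        - 0.03
        - 0.0
      - - 0.0
        - 0.96
        - 0.04
      - - 0.0
        - 0.0
        - 1.0
utilities:
  u_preprog_early: 0.81
  u_preprog_late: 0.77
  late_switch_cycle: 27
  u_prog: 0.64
  u_dead: 0.0
cets:
  primary_cet: 38500.0
  low_cet: 32659.0
  high_cet: 131006.0
cost_accrual_states:
- pre_progression
- progression
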