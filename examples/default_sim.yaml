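# Default synthetic-claims configuration: 50,000 insured persons over
# calendar years 2006-2014 with the noise channels the identification
# algorithms are designed around (suspected-only V coding, sporadically
# coded prevalent cases, recurrence after a latency, watchful waiting for
# prostate cancer, stray erroneous codes, coverage gaps).  See
# docs/methods.md for the rationale behind each value.
n_persons: 50000
seed: 20130101
first_year: 2006
last_year: 2014
sex_female_prob: 0.55
birth_year_bands:
- - 1919
  - 1928
  - 0.03
- - 1929
  - 1938
  - 0.08
- - 1939
  - 1948
  - 0.13
- - 1949
  - 1958
  - 0.17
- - 1959
  - 1968
  - 0.17
- - 1969
  - 1978
  - 0.14
- - 1979
  - 1988
  - 0.12
- - 1989
  - 1998
  - 0.09
- - 1999
  - 2008
  - 0.07
state_probs:
- - NW
  - 0.215
- - BY
  - 0.157
- - BW
  - 0.133
- - NI
  - 0.096
- - HE
  - 0.075
- - SN
  - 0.05
- - RP
  - 0.049
- - BE
  - 0.043
- - SH
  - 0.035
- - BB
  - 0.03
- - ST
  - 0.027
- - TH
  - 0.026
- - HH
  - 0.022
- - MV
  - 0.02
- - SL
  - 0.012
- - HB
  - 0.01
p_foreign: 0.003
p_missing_state: 0.004
p_missing_sex: 0.0002
p_missing_birth_year: 0.001
enrollment:
  p_full_span: 0.85
  gap_prob: 0.08
  gap_mean_days: 30.0
coding:
  p_index_coded: 0.95
  p_index_inpatient: 0.35
  p_followup_g: 0.8
  followup_quarters: 4
  p_inpatient_ancillary: 0.08
  z_after_treatment: 0.4
  z_surveillance_quarters: 12
  z_long_term: 0.15
  prevalent_coding_rate: 0.12
  prevalent_g_share: 0.5
  suspected_only_rate: 0.01
  stray_code_rate: 0.001
  ww_coding_factor: 0.35
disease:
  BREAST:
    hazard_by_age:
    - - 0
      - 2.0e-06
    - - 30
      - 0.00012
    - - 50
      - 0.00075
    - - 70
      - 0.00085
    prevalence_at_start: 0.015
    recurrence_prob: 0.15
    recurrence_latency_mean_q: 8.0
    case_fatality_per_quarter: 0.009
    surgery_prob: 0.75
    recurrence_surgery_prob: 0.3
    surgery_delay_mean_q: 0.5
    watchful_waiting_fraction: 0.0
  PROSTATE:
    hazard_by_age:
    - - 0
      - 1.0e-06
    - - 50
      - 0.0006
    - - 70
      - 0.0011
    prevalence_at_start: 0.012
    recurrence_prob: 0.12
    recurrence_latency_mean_q: 10.0
    case_fatality_per_quarter: 0.007
    surgery_prob: 0.0
    recurrence_surgery_prob: 0.0
    surgery_delay_mean_q: 0.5
    watchful_waiting_fraction: 0.25
  COLORECTAL:
    hazard_by_age:
    - - 0
      - 2.0e-06
    - - 50
      - 0.00022
    - - 70
      - 0.00065
    prevalence_at_start: 0.006
    recurrence_prob: 0.15
    recurrence_latency_mean_q: 8.0
    case_fatality_per_quarter: 0.028
    surgery_prob: 0.85
    recurrence_surgery_prob: 0.35
    surgery_delay_mean_q: 0.5
    watchful_waiting_fraction: 0.0
mortality_a: 4.0e-05
mortality_b: 0.09
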