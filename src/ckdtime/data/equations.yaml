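# Estimating-equation constants and urine-biomarker conversion models.
#
# schwartz / ckdepi2021 / u25 constants are transcribed from the primary
# publications of each equation (Schwartz 2009; Inker 2021; Pierce 2021).
# The dipstick_to_acr map and acr_pcr coefficients are SYNTHETIC defaults:
# monotone placeholders with the published equations' functional form, meant
# to be replaced by validated coefficients via a user config without any
# code change.

schwartz:
  k: 0.413

ckdepi2021:
  scale: 142.0
  kappa: {female: 0.7, male: 0.9}
  alpha: {female: -0.241, male: -0.302}
  exponent_high: -1.200
  age_factor: 0.9938
  female_factor: 1.012

# k(age, sex) = k_base * per_year_factor ** (age - ref_age), height in metres.
u25:
  - {sex: male,   age_lo: 1.0,  age_hi: 12.0, k_base: 39.0, per_year_factor: 1.008, ref_age: 12.0}
  - {sex: male,   age_lo: 12.0, age_hi: 18.0, k_base: 39.0, per_year_factor: 1.045, ref_age: 12.0}
  - {sex: male,   age_lo: 18.0, age_hi: 25.0, k_base: 50.8, per_year_factor: 1.0,   ref_age: 18.0}
  - {sex: female, age_lo: 1.0,  age_hi: 12.0, k_base: 36.1, per_year_factor: 1.008, ref_age: 12.0}
  - {sex: female, age_lo: 12.0, age_hi: 18.0, k_base: 36.1, per_year_factor: 1.023, ref_age: 12.0}
  - {sex: female, age_lo: 18.0, age_hi: 25.0, k_base: 41.4, per_year_factor: 1.0,   ref_age: 18.0}

# Ordinal dipstick category -> ACR mg/g (synthetic monotone defaults).
dipstick_to_acr:
  negative: 10.0
  trace: 50.0
  "1+": 150.0
  "2+": 500.0
  "3+": 1000.0
  "4+": 2000.0

# PCR = exp(log_intercept) * ACR ** log_slope, per age group (synthetic defaults).
acr_pcr:
  - {age_lo: 0.0,  age_hi: 18.0, log_intercept: 0.5877866649021191, log_slope: 1.0}
  - {age_lo: 18.0, age_hi: 26.0, log_intercept: 0.5877866649021191, log_slope: 1.0}
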