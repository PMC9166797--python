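# Packaged cohort configuration: acute myocardial infarction (AMI).
# Marginal summaries of the derivation (1999-2001 discharges, N=8145) and
# validation (2004-2005 discharges, N=4444) samples. Continuous variables:
# mean and SD; binary variables: prevalence as a proportion.
# The validation prevalence of cardiogenic shock was suppressed at source
# (cell count <= 5); it is imputed here at 0.005 and flagged.
cohort_id: ami
n_derivation: 8145
n_validation: 4444
correlation:
  mode: exchangeable
  rho: 0.2
outcome:
  name: discharge_sbp
  kind: continuous
  derivation: {mean: 120.40, sd: 19.69}
  validation: {mean: 122.48, sd: 20.60}
variables:
  - name: age
    kind: continuous
    derivation: {mean: 66.51, sd: 13.58}
    validation: {mean: 69.13, sd: 14.32}
  - name: female
    kind: binary
    derivation: {prevalence: 0.343}
    validation: {prevalence: 0.385}
  - name: presenting_sbp
    kind: continuous
    derivation: {mean: 148.87, sd: 31.15}
    validation: {mean: 144.64, sd: 31.24}
  - name: presenting_dbp
    kind: continuous
    derivation: {mean: 83.86, sd: 18.46}
    validation: {mean: 80.39, sd: 18.42}
  - name: heart_rate
    kind: continuous
    derivation: {mean: 83.61, sd: 23.77}
    validation: {mean: 85.72, sd: 23.74}
  - name: respiratory_rate
    kind: continuous
    derivation: {mean: 20.86, sd: 5.45}
    validation: {mean: 20.41, sd: 5.32}
  - name: cardiogenic_shock
    kind: binary
    derivation: {prevalence: 0.007}
    validation: {prevalence: 0.005, imputed: true}
  - name: acute_chf_pulmonary_edema
    kind: binary
    derivation: {prevalence: 0.048}
    validation: {prevalence: 0.066}
  - name: diabetes
    kind: binary
    derivation: {prevalence: 0.254}
    validation: {prevalence: 0.285}
  - name: hypertension
    kind: binary
    derivation: {prevalence: 0.458}
    validation: {prevalence: 0.598}
  - name: current_smoker
    kind: binary
    derivation: {prevalence: 0.338}
    validation: {prevalence: 0.272}
  - name: dyslipidemia
    kind: binary
    derivation: {prevalence: 0.319}
    validation: {prevalence: 0.451}
  - name: family_history_cad
    kind: binary
    derivation: {prevalence: 0.320}
    validation: {prevalence: 0.310}
  - name: cva_tia
    kind: binary
    derivation: {prevalence: 0.095}
    validation: {prevalence: 0.131}
  - name: angina
    kind: binary
    derivation: {prevalence: 0.330}
    validation: {prevalence: 0.306}
  - name: cancer
    kind: binary
    derivation: {prevalence: 0.028}
    validation: {prevalence: 0.018}
  - name: dementia
    kind: binary
    derivation: {prevalence: 0.031}
    validation: {prevalence: 0.060}
  - name: peptic_ulcer_disease
    kind: binary
    derivation: {prevalence: 0.055}
    validation: {prevalence: 0.051}
  - name: previous_ami
    kind: binary
    derivation: {prevalence: 0.224}
    validation: {prevalence: 0.256}
  - name: asthma
    kind: binary
    derivation: {prevalence: 0.055}
    validation: {prevalence: 0.063}
  - name: depression
    kind: binary
    derivation: {prevalence: 0.069}
    validation: {prevalence: 0.109}
  - name: peripheral_vascular_disease
    kind: binary
    derivation: {prevalence: 0.072}
    validation: {prevalence: 0.090}
  - name: previous_revascularization
    kind: binary
    derivation: {prevalence: 0.092}
    validation: {prevalence: 0.136}
  - name: congestive_heart_failure
    kind: binary
    derivation: {prevalence: 0.041}
    validation: {prevalence: 0.064}
  - name: hyperthyroidism
    kind: binary
    derivation: {prevalence: 0.013}
    validation: {prevalence: 0.003}
  - name: aortic_stenosis
    kind: binary
    derivation: {prevalence: 0.015}
    validation: {prevalence: 0.019}
  - name: hemoglobin
    kind: continuous
    derivation: {mean: 138.70, sd: 18.67}
    validation: {mean: 135.66, sd: 20.66}
  - name: wbc
    kind: continuous
    derivation: {mean: 10.23, sd: 4.83}
    validation: {mean: 10.43, sd: 4.27}
  - name: sodium
    kind: continuous
    derivation: {mean: 139.03, sd: 3.75}
    validation: {mean: 138.62, sd: 3.93}
  - name: potassium
    kind: continuous
    derivation: {mean: 4.09, sd: 0.55}
    validation: {mean: 4.11, sd: 0.58}
  - name: glucose
    kind: continuous
    derivation: {mean: 9.37, sd: 5.21}
    validation: {mean: 9.01, sd: 4.53}
  - name: urea
    kind: continuous
    derivation: {mean: 7.38, sd: 4.53}
    validation: {mean: 8.13, sd: 5.40}
  - name: creatinine
    kind: continuous
    derivation: {mean: 103.60, sd: 58.77}
    validation: {mean: 111.64, sd: 72.95}
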