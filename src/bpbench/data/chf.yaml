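# Packaged cohort configuration: congestive heart failure (CHF).
# Marginal summaries of the derivation (1999-2001 discharges, N=7156) and
# validation (2004-2005 discharges, N=6818) samples. Continuous variables:
# mean and SD; binary variables: prevalence as a proportion.
cohort_id: chf
n_derivation: 7156
n_validation: 6818
correlation:
  mode: exchangeable
  rho: 0.2
outcome:
  name: discharge_sbp
  kind: continuous
  derivation: {mean: 124.87, sd: 22.27}
  validation: {mean: 125.77, sd: 21.94}
variables:
  - name: age
    kind: continuous
    derivation: {mean: 75.20, sd: 11.54}
    validation: {mean: 76.23, sd: 11.58}
  - name: female
    kind: binary
    derivation: {prevalence: 0.500}
    validation: {prevalence: 0.507}
  - name: presenting_sbp
    kind: continuous
    derivation: {mean: 150.41, sd: 33.22}
    validation: {mean: 148.42, sd: 32.27}
  - name: heart_rate
    kind: continuous
    derivation: {mean: 94.46, sd: 25.30}
    validation: {mean: 92.36, sd: 25.73}
  - name: respiratory_rate
    kind: continuous
    derivation: {mean: 25.96, sd: 7.25}
    validation: {mean: 24.45, sd: 6.91}
  - name: neck_vein_distension
    kind: binary
    derivation: {prevalence: 0.551}
    validation: {prevalence: 0.608}
  - name: s3
    kind: binary
    derivation: {prevalence: 0.099}
    validation: {prevalence: 0.063}
  - name: s4
    kind: binary
    derivation: {prevalence: 0.038}
    validation: {prevalence: 0.028}
  - name: rales_gt_50pct
    kind: binary
    derivation: {prevalence: 0.103}
    validation: {prevalence: 0.124}
  - name: pulmonary_edema
    kind: binary
    derivation: {prevalence: 0.516}
    validation: {prevalence: 0.606}
  - name: cardiomegaly
    kind: binary
    derivation: {prevalence: 0.357}
    validation: {prevalence: 0.442}
  - name: diabetes
    kind: binary
    derivation: {prevalence: 0.349}
    validation: {prevalence: 0.379}
  - name: cerebrovascular_disease_tia
    kind: binary
    derivation: {prevalence: 0.160}
    validation: {prevalence: 0.179}
  - name: previous_ami
    kind: binary
    derivation: {prevalence: 0.369}
    validation: {prevalence: 0.368}
  - name: atrial_fibrillation
    kind: binary
    derivation: {prevalence: 0.289}
    validation: {prevalence: 0.352}
  - name: peripheral_vascular_disease
    kind: binary
    derivation: {prevalence: 0.125}
    validation: {prevalence: 0.134}
  - name: copd
    kind: binary
    derivation: {prevalence: 0.164}
    validation: {prevalence: 0.223}
  - name: dementia
    kind: binary
    derivation: {prevalence: 0.066}
    validation: {prevalence: 0.092}
  - name: cirrhosis
    kind: binary
    derivation: {prevalence: 0.007}
    validation: {prevalence: 0.008}
  - name: cancer
    kind: binary
    derivation: {prevalence: 0.112}
    validation: {prevalence: 0.111}
  - name: left_bundle_branch_block
    kind: binary
    derivation: {prevalence: 0.148}
    validation: {prevalence: 0.134}
  - name: hemoglobin
    kind: continuous
    derivation: {mean: 124.17, sd: 20.65}
    validation: {mean: 123.23, sd: 20.53}
  - name: wbc
    kind: continuous
    derivation: {mean: 9.89, sd: 5.23}
    validation: {mean: 9.65, sd: 4.24}
  - name: sodium
    kind: continuous
    derivation: {mean: 138.37, sd: 4.74}
    validation: {mean: 138.43, sd: 4.86}
  - name: potassium
    kind: continuous
    derivation: {mean: 4.28, sd: 0.66}
    validation: {mean: 4.26, sd: 0.66}
  - name: glucose
    kind: continuous
    derivation: {mean: 9.03, sd: 4.69}
    validation: {mean: 8.61, sd: 4.08}
  - name: urea
    kind: continuous
    derivation: {mean: 10.00, sd: 6.32}
    validation: {mean: 9.92, sd: 6.04}
  - name: creatinine
    kind: continuous
    derivation: {mean: 129.63, sd: 94.43}
    validation: {mean: 126.42, sd: 81.08}
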