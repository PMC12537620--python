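# Sex-specific risk-factor parameters: survivor prevalences (%), joint
# exposure, and relative risks (point estimate, 95% CI) for late-life
# smoking and mid-life hypertension.
# Provenance: published Dutch national-statistics prevalence estimates,
# cohort-study co-occurrence, and systematic-review risk ratios, as printed
# in the source parameter table. Hypertension prevalence reflects
# unmedicated hypertension; the medication share is carried for reference.
female:
  prev_smoking: {point: 10.0, ci: [8.6, 11.7]}
  prev_hypertension: {point: 10.0, ci: [9.8, 10.1]}
  prev_hypertension_medication: 1.7
  prev_both: {point: 2.4, ci: [2.1, 2.8]}
  cooccurrence_smokers_with_hypertension: 0.24
  rr_mortality_smoking: {point: 1.9, ci: [1.7, 2.1]}
  rr_mortality_hypertension: {point: 1.3, ci: [1.1, 1.7]}
  rr_dementia_smoking: {point: 1.6, ci: [1.2, 2.2]}
  rr_dementia_hypertension: {point: 1.6, ci: [1.2, 2.2]}
male:
  prev_smoking: {point: 13.8, ci: [12.1, 15.6]}
  prev_hypertension: {point: 9.3, ci: [9.2, 9.5]}
  prev_hypertension_medication: 1.1
  prev_both: {point: 4.3, ci: [3.8, 4.8]}
  cooccurrence_smokers_with_hypertension: 0.31
  rr_mortality_smoking: {point: 1.8, ci: [1.6, 2.0]}
  rr_mortality_hypertension: {point: 1.3, ci: [1.1, 1.7]}
  rr_dementia_smoking: {point: 1.6, ci: [1.2, 2.2]}
  rr_dementia_hypertension: {point: 1.6, ci: [1.2, 2.2]}
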