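# Base-case scenario set: reference plus 10/25/50/100% prevalence
# reductions of each risk factor singly and of both factors jointly.
scenarios:
  - {label: reference, reduce_smoking: 0.0, reduce_hypertension: 0.0}
  - {label: smoking_10, reduce_smoking: 0.10, reduce_hypertension: 0.0}
  - {label: smoking_25, reduce_smoking: 0.25, reduce_hypertension: 0.0}
  - {label: smoking_50, reduce_smoking: 0.50, reduce_hypertension: 0.0}
  - {label: smoking_100, reduce_smoking: 1.0, reduce_hypertension: 0.0}
  - {label: hypertension_10, reduce_smoking: 0.0, reduce_hypertension: 0.10}
  - {label: hypertension_25, reduce_smoking: 0.0, reduce_hypertension: 0.25}
  - {label: hypertension_50, reduce_smoking: 0.0, reduce_hypertension: 0.50}
  - {label: hypertension_100, reduce_smoking: 0.0, reduce_hypertension: 1.0}
  - {label: both_10, reduce_smoking: 0.10, reduce_hypertension: 0.10}
  - {label: both_25, reduce_smoking: 0.25, reduce_hypertension: 0.25}
  - {label: both_50, reduce_smoking: 0.50, reduce_hypertension: 0.50}
  - {label: both_100, reduce_smoking: 1.0, reduce_hypertension: 1.0}
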