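# Risk-factor -> disease mapping used when combining PIFs per disease.
# Editable data, not code: BMI acts on all six modelled diseases; dietary
# factors act on their cardiometabolic outcomes.  The processed-sugar
# pathway to stomach/colorectal cancer runs through BMI only.
sugar: [type_2_diabetes]
ssb: [type_2_diabetes, ischemic_heart_disease]
sfa: [ischemic_heart_disease, ischemic_stroke]
tfa: [ischemic_heart_disease, ischemic_stroke]
bmi:
  - ischemic_heart_disease
  - ischemic_stroke
  - type_2_diabetes
  - osteoarthritis
  - colorectal_cancer
  - stomach_cancer
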