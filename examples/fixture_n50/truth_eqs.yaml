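AMPUTATION:
  coefficients:
    diabetes_duration: 0.02
    hist_ULCER: 1.0
    intercept: -5.988961416889864
  form: logistic
  second_event: true
BLINDNESS:
  coefficients:
    diabetes_duration: 0.02
    intercept: -5.806138481293728
  form: logistic
  second_event: false
CHF:
  coefficients:
    age: 0.06
    hist_IHD: 0.3
    hist_MI: 0.6
    intercept: -8.31511985013459
  form: logistic
  second_event: false
DEATH:
  coefficients:
    age: 0.08
    hist_AMPUTATION: 0.6
    hist_CHF: 0.6
    hist_MI: 0.5
    hist_RENAL_FAILURE: 0.9
    hist_STROKE: 0.5
    intercept: -9.370776047959868
    new_MI: 1.2
    new_STROKE: 1.2
  form: logistic
IHD:
  coefficients:
    age: 0.03
    hist_MI: 0.4
    intercept: -6.45511985013459
  form: logistic
  second_event: false
MI:
  coefficients:
    age: 0.04
    female: -0.3
    hist_IHD: 0.5
    hist_MI: 0.6
    hist_STROKE: 0.3
    intercept: -6.734599024987377
  form: logistic
  second_event: true
RENAL_FAILURE:
  coefficients:
    diabetes_duration: 0.02
    intercept: -5.806138481293728
  form: logistic
  second_event: false
STROKE:
  coefficients:
    age: 0.05
    hist_MI: 0.3
    hist_STROKE: 0.7
    intercept: -7.920281565605038
  form: logistic
  second_event: true
ULCER:
  coefficients:
    diabetes_duration: 0.02
    intercept: -5.109977737428519
  form: logistic
  second_event: false
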