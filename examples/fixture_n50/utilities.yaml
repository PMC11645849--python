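baseline_utility: 0.807
decrements:
  AMPUTATION:
    event_year: 0.28
    subsequent: 0.28
  BLINDNESS:
    event_year: 0.0
    subsequent: 0.0
  CHF:
    event_year: 0.108
    subsequent: 0.108
  IHD:
    event_year: 0.0
    subsequent: 0.0
  MI:
    event_year: 0.065
    subsequent: 0.0
  RENAL_FAILURE:
    event_year: 0.33
    subsequent: 0.33
  STROKE:
    event_year: 0.165
    subsequent: 0.165
  ULCER:
    event_year: 0.17
    subsequent: 0.17
max_counted:
  AMPUTATION: 2
  BLINDNESS: 1
  CHF: 1
  IHD: 1
  MI: 2
  RENAL_FAILURE: 1
  STROKE: 2
  ULCER: 1
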