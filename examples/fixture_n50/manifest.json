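{
  "seed": 2024,
  "n_patients": 50,
  "max_follow_up_years": 7.0,
  "files": [
    "patients.csv",
    "events.csv",
    "truth_eqs.yaml",
    "utilities.yaml"
  ]
}
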