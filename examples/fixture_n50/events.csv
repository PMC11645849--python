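patient_id,event_type,occurrence_index,year_index
5,ULCER,1,3
14,IHD,1,3
14,RENAL_FAILURE,1,3
14,CHF,1,4
23,MI,1,3
25,AMPUTATION,1,2
26,CHF,1,2
26,MI,1,5
27,STROKE,1,4
38,CHF,1,3
40,MI,1,2
44,CHF,1,1
46,CHF,1,3
47,CHF,1,2
48,ULCER,1,4
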