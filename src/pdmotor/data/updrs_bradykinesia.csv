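subject_id,item23_finger_tapping_off,item23_finger_tapping_on,item25_pronosupination_off,item25_pronosupination_on
S1,3,3,2,2
S2,2,1,1,1
S3,1,0,1,0
S4,2,1,2,1
S5,1,1,1,1
S6,3,2,4,4
S7,1,0,1,0
S8,3,2,2,2
S9,2,1,1,1
S10,1,1,1,1
S11,2,1,1,0
S12,2,1,2,1
S13,1,1,1,1
S14,3,2,1,1
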