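subject_id,item22_right_off,item22_right_on,item22_left_off,item22_left_on
S1,2,2,2,2
S2,2,1,2,1
S3,2,2,2,2
S4,2,1,1,1
S5,2,1,2,2
S6,2,2,2,2
S7,1,0,1,1
S8,2,2,3,2
S9,0,0,0,0
S10,2,1,2,1
S11,1,1,2,1
S12,1,1,2,2
S13,1,1,2,1
S14,2,2,1,1
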