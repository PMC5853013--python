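subject_id,disease_duration_years,gender,dominant_hand,most_affected_side,ledd_mg,updrs3_total_off
S1,10,M,Right,Right,750,45
S2,5,M,Right,Left,750,29
S3,9,F,Right,Left,950,29
S4,7,F,Right,Right,660,36
S5,21,F,Right,Left,660,29
S6,10,M,Right,Right,925,65
S7,4,F,Right,Left,550,23
S8,,M,Left,Left,,49
S9,7,M,Right,Right,700,20
S10,2,F,Right,Right,300,25
S11,7,F,Right,Left,1150,29
S12,6,M,Right,Left,600,25
S13,10,M,Right,Left,700,27
S14,7,M,Right,Right,670,43
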