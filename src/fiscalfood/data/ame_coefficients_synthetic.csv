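age_lo,age_hi,male,female
0,3,0.30,0.30
4,6,0.55,0.55
7,9,0.70,0.70
10,13,0.85,0.80
14,17,0.95,0.85
18,30,1.00,0.80
31,60,0.95,0.78
61,120,0.85,0.72
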