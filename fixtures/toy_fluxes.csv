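reaction,flux
v1,3.0
v2,1.0
v3,1.0
v4_f,0.5
v4_b,0.5
v5_f,2.0
v5_b,1.0
v6,1.0
e_C,1.0
e_D,1.0
e_E,2.0
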