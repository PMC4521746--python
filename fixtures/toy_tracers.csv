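metabolite,isotopomer,fraction
A,1100,0.5
A,0000,0.5
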