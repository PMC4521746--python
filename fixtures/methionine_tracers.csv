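metabolite,isotopomer,fraction
Met_media,11111,0.5
Met_media,00000,0.5
ATP,0000000000,1.0
CH3_THF,0,1.0
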