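# Toy network: media metabolite A (4 carbons) feeds B, C, D, E.
# v2 splits A into two 2-carbon halves (the D half written reversed);
# v3 transfers the B 3,4-carbon unit onto C; v6 condenses that unit with C.
#media A
v1: A (abcd) -> B (abcd)
v2: A (abcd) -> C (ab) + D (dc)
v3: B (abcd) -> C (cd)
v4: C (ab) <-> D (ab)
v5: B (abcd) <-> E (abcd)
v6: B (abcd) + C (ef) -> E (cdef)
e_C: C (ab) ->
e_D: D (ab) ->
e_E: E (abcd) ->
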