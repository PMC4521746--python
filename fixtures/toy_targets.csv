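metabolite,parent_atoms,product_atoms
E,"1,2,3,4","2,3"
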