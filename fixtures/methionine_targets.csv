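metabolite,parent_atoms,product_atoms
Met,"1,2,3,4,5","1,2,3,4"
SAM,"1,2,3,4,5,6,7,8,9,10,11,12,13,14,15","6,7,8,9,10"
SAH,"1,2,3,4,5,6,7,8,9,10,11,12,13,14","5,6,7,8,9"
MTA,"1,2,3,4,5,6,7,8,9,10,11","2,3,4,5,6"
HCys,"1,2,3,4","1,2,3,4"
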