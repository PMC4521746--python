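reaction,flux
upt,3.0
mat,10.0
mt,7.0
sahh,7.0
ms,5.0
poly,3.0
salv,3.0
prot,1.0
ts,2.0
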