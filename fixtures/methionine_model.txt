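#media Met_media ATP CH3_THF
upt: Met_media (abcde) -> Met (abcde)
mat: Met (abcde) + ATP (fghijklmno) -> SAM (abcdefghijklmno)
mt: SAM (abcdefghijklmno) -> SAH (abcdfghijklmno)
sahh: SAH (abcdefghijklmn) -> HCys (abcd)
ms: HCys (abcd) + CH3_THF (e) -> Met (abcde)
poly: SAM (abcdefghijklmno) -> MTA (efghijklmno)
salv: MTA (abcdefghijk) -> Met (hijka)
prot: Met (abcde) ->
ts: HCys (abcd) ->
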