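NONPBR_E1:
- 0
- 24
PBR_alpha1:
- 24
- 114
PBR_alpha2:
- 114
- 206
NONPBR_E4:
- 206
- 298
NONPBR_E5:
- 298
- 335
NONPBR_E6:
- 335
- 346
NONPBR_E7:
- 346
- 357
NONPBR_E8:
- 357
- 362
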