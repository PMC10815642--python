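{
  "A": [6, 58, 158],
  "B": [6],
  "D": [158],
  "F": [83, 122, 145]
}
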