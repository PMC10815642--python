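{
  "A": [5, 6, 9, 58, 63, 66, 158, 159, 163, 167],
  "B": [6, 7, 9, 24, 25, 33, 34, 45, 60, 70],
  "C": [9, 70, 73, 74, 97],
  "D": [99, 114, 155, 156, 158, 160],
  "E": [97, 114, 147, 152, 156],
  "F": [77, 80, 81, 83, 84, 95, 116, 122, 123, 143, 145, 146]
}
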