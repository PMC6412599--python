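{
  "R": {
    "R": 2,
    "C": 1,
    "NR": -2
  },
  "C": {
    "R": 1,
    "C": 2,
    "NR": -1
  },
  "NR": {
    "R": -2,
    "C": -1,
    "NR": 2
  }
}
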