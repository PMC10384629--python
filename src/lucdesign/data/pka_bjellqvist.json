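{
  "comment": "Bjellqvist-style pKa values used for theoretical pI. Overridable via config.",
  "n_terminus": 7.5,
  "c_terminus": 3.55,
  "positive": {
    "K": 10.0,
    "R": 12.0,
    "H": 5.98
  },
  "negative": {
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0
  }
}
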