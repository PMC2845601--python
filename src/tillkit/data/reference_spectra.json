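{
  "barley": {
    "GC/AT": 70.0,
    "GC/TA": 10.0,
    "AT/TA": 10.0,
    "AT/GC": 10.0,
    "AT/CG": 0.0,
    "GC/CG": 0.0
  },
  "rice": {
    "GC/AT": 70.0,
    "GC/TA": 4.0,
    "AT/TA": 15.0,
    "AT/GC": 11.0,
    "AT/CG": 0.0,
    "GC/CG": 0.0
  }
}
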