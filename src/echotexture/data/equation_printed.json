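{
  "intercept": 281.89031,
  "coefficients": {
    "S(2,2)InvDfMom": -208.07129,
    "S(3,-3)Contrast": 0.14783,
    "S(4,-4)DifEntrp": -85.60868,
    "45dgr_ShrtREmp": -180.22176,
    "GrKurtosis": 1.11743,
    "Teta2": -44.34882,
    "Teta4": 49.86069
  }
}
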