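areas:
  A: 123.80494905385736
  C: 160.2746239689471
  D: 185.22755943716643
  E: 214.01940805434256
  F: 230.33478893740903
  G: 99.81174187287725
  H: 214.97913634158178
  I: 189.06647258612327
  K: 226.49587578845222
  L: 192.90538573508007
  M: 214.97913634158178
  N: 187.14701601164484
  P: 152.5967976710335
  Q: 215.93886462882097
  R: 262.96555070354196
  S: 148.75788452207667
  T: 165.07326540514313
  V: 166.99272197962156
  W: 273.5225618631732
  Y: 252.40853954391073
calibration_factor: 0.9597282872392043
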