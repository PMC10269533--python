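>anchor_tm_synthetic synthetic single-pass membrane-regulator calibration anchor; TM=172-194
DKAVAVSKVFWWSQEPTWVFWFNGVIDAKIGPKGLGRCMTLIDGPPEAKGLGWGKVSSQI
EPKAWEMAGKVWGQWVKSQEKRPRKTECLKAATSSTGEGGHWGVRWKAAEEQEVTWNGKE
VTPEGPSFGRNEGAIFHTTGKKIRSKHANWPGCLESLQQQVPLSWDVILTLLAIGFLVAL
IVLFAGLIAVLILLYVSNVQMWTSPWVTVQAPIPGTLGIWK
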