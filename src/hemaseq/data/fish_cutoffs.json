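{
  "TCF3 3 copies": {"100": 2.0, "200": 1.5, "300": 1.3},
  "CDKN2A tetrasomy": {"100": 1.0, "200": 1.0, "300": 1.0},
  "RUNX1 3 copies": {"100": 1.0, "200": 0.5, "300": 0.3},
  "MLL 3 copies": {"100": 1.0, "200": 0.5, "300": 0.3},
  "PML 3 copies": {"100": 0.0, "200": 0.5, "300": 0.3},
  "CEP8 3 copies": {"100": 2.0, "200": 1.5, "300": 1.3},
  "20q deletion": {"100": 3.0, "200": 2.0, "300": 1.7}
}
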