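{
  "name": "composite",
  "root": "HSC",
  "children": {
    "HSC": ["MPP"],
    "MPP": ["LMPP", "MEP"],
    "LMPP": ["MLP", "GMP"]
  },
  "leaf_slots": {
    "PC": "MLP",
    "lymphocyte": "MLP",
    "MB": "GMP",
    "neutrophil": "GMP",
    "eosinophil": "GMP",
    "erythrocyte": "MEP",
    "megakaryocyte": "MEP",
    "other": "MPP"
  }
}
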