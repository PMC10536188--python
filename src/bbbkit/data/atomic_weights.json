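{
  "_comment": "IUPAC 2021 conventional (abridged) standard atomic weights, g/mol",
  "H": 1.008,
  "B": 10.81,
  "C": 12.011,
  "N": 14.007,
  "O": 15.999,
  "F": 18.998,
  "Na": 22.99,
  "Mg": 24.305,
  "P": 30.974,
  "S": 32.06,
  "Cl": 35.45,
  "K": 39.098,
  "Ca": 40.078,
  "Fe": 55.845,
  "Zn": 65.38,
  "Br": 79.904,
  "I": 126.904
}
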