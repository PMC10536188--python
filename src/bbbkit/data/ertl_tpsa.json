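{
  "_comment": "Ertl fragment contributions to topological polar surface area, A^2. O- and N-containing fragments only; S/P contributions are an extension point. Composite groups are sums of the published single-atom fragments (carboxylic_acid = carbonyl O 17.07 + hydroxyl 20.23; ester = carbonyl O 17.07 + ether O 9.23).",
  "hydroxyl": 20.23,
  "carbonyl_O": 17.07,
  "ether_O": 9.23,
  "aromatic_O": 13.14,
  "carboxylic_acid": 37.3,
  "ester": 26.3,
  "amine_N": 26.02,
  "amine_N_primary": 26.02,
  "amine_N_secondary": 12.03,
  "amine_N_tertiary": 3.24,
  "aromatic_N": 12.89,
  "aromatic_NH": 15.79,
  "amide": 29.1,
  "amide_primary": 43.09,
  "nitrile": 23.79,
  "nitro": 45.82
}
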