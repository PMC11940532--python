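{
  "_comment": "IUPAC 2021 standard atomic weights (conventional single values where IUPAC gives an interval), g/mol.",
  "H": 1.008,
  "B": 10.81,
  "C": 12.011,
  "N": 14.007,
  "O": 15.999,
  "F": 18.998403163,
  "Na": 22.98976928,
  "Mg": 24.305,
  "Al": 26.9815384,
  "Si": 28.085,
  "P": 30.973761998,
  "S": 32.06,
  "Cl": 35.45,
  "K": 39.0983,
  "Ca": 40.078,
  "Mn": 54.938043,
  "Fe": 55.845,
  "Cu": 63.546,
  "Zn": 65.38,
  "Se": 78.971,
  "Br": 79.904,
  "I": 126.90447,
  "Li": 6.94
}
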