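{
  "model": "angiogenesis64",
  "description": "Companion metadata for the 64-node angiogenesis endothelial-cell model: micro-environment inputs (in environment-code bit order, first entry = most significant bit), behavior marker signatures, the proliferation requirement, and display-name aliases.",
  "inputs": [
    "VEGFC_Dp",
    "VEGFAxxxP",
    "ANG1",
    "Oxygen",
    "ShearStress",
    "JAGp",
    "DLL4p",
    "WNT5a",
    "WNT7a",
    "FGF",
    "IGF",
    "BMP9",
    "BMP10",
    "TGFB1",
    "VEGFC_D",
    "AMPATP"
  ],
  "signatures": {
    "Tip": {"NRP1": 1, "DLL4a": 1, "AKT": 0},
    "Stalk": {"JAGa": 1, "NRP1": 0},
    "Phalanx": {"AKT": 1, "JAGa": 0, "NRP1": 0}
  },
  "proliferation": {"betacatenin": 1, "LEF1": 1},
  "aliases": {"betacatenin": "βcatenin"}
}
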