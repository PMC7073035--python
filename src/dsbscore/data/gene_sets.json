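{
  "dsb": {
    "NHEJ": [
      ["XRCC5", "determinant"],
      ["XRCC6", "determinant"],
      ["TP53BP1", "protection"],
      ["WRN", "protection"]
    ],
    "MMEJ": [
      ["PARP1", "determinant"],
      ["RBBP8", "resection"],
      ["MRE11", "resection"],
      ["NBN", "resection"],
      ["RAD50", "resection"]
    ],
    "HDR": [
      ["BRCA1", "determinant"],
      ["BRCA2", "determinant"],
      ["RAD51", "determinant"],
      ["PALB2", "determinant"],
      ["RPA1", "SSA"],
      ["RPA2", "SSA"],
      ["EXO1", "add-resection"],
      ["BLM", "add-resection"]
    ]
  },
  "protein_aliases": {
    "XRCC5": "Ku80",
    "XRCC6": "Ku70",
    "RBBP8": "CtIP"
  },
  "mouse_overrides": {
    "TP53BP1": "Trp53bp1",
    "MRE11": "Mre11a"
  },
  "cell_cycle": {
    "G2M": [
      "CDK1", "CCNB1", "CCNB2", "PLK1", "AURKA", "AURKB", "BUB1", "BUB1B",
      "CDC20", "CDC25C", "TOP2A", "UBE2C", "KIF11", "KIF23", "CENPA",
      "CENPE", "CENPF", "TPX2", "MKI67", "BIRC5"
    ],
    "S": [
      "MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7", "PCNA", "RRM1",
      "RRM2", "CDC6", "CDC45", "GINS2", "FEN1", "TYMS", "POLA1", "PRIM1",
      "E2F1", "CLSPN", "DTL", "UHRF1"
    ]
  },
  "retinal_markers": {
    "progenitor": ["VSX2", "SOX2", "HES1", "HES5", "SFRP2", "CCND1", "ID3", "LHX2", "PAX6", "ZIC1"],
    "neuroblast": ["ATOH7", "NEUROD1", "NEUROG2", "HES6", "DLL3", "PRDM1", "OTX2", "BTG2", "GADD45A", "PENK"],
    "cone": ["ARR3", "GNAT2", "PDE6H", "OPN1SW", "OPN1MW", "GNGT2", "GUCA1C", "PDE6C", "THRB", "RXRG"],
    "rod": ["RHO", "GNAT1", "NR2E3", "NRL", "PDE6B", "PDE6A", "CNGA1", "ROM1", "SAG", "GNGT1"],
    "muller_glia": ["SLC1A3", "RLBP1", "GLUL", "APOE", "CLU", "AQP4", "VIM", "S100B"],
    "amacrine": ["TFAP2A", "TFAP2B", "GAD1", "GAD2", "SLC32A1", "CALB2", "CHAT", "SLC6A9"],
    "retinal_ganglion": ["RBPMS", "POU4F2", "ISL1", "SNCG", "NEFL", "NEFM", "GAP43", "POU4F1"],
    "bipolar": ["VSX1", "CABP5", "GRM6", "PRKCA", "TRPM1", "PCP2", "CADPS", "LRTM1"]
  }
}
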