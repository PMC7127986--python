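{
  "_note": "Synthetic subset of an approved-gene-symbol table in the non_alt_loci_set JSON layout. Real cancer gene symbols plus a few clearly synthetic entries (GENE1, GENE2) exercising alias ambiguity.",
  "response": {
    "docs": [
      {"symbol": "ERBB2", "alias_symbol": ["NEU", "HER-2", "HER2", "CD340"], "prev_symbol": ["NGL"]},
      {"symbol": "BRAF", "alias_symbol": ["BRAF1", "RAFB1"], "prev_symbol": []},
      {"symbol": "KRAS", "alias_symbol": ["KRAS2", "K-RAS"], "prev_symbol": ["KRAS1"]},
      {"symbol": "EGFR", "alias_symbol": ["ERBB1", "HER1"], "prev_symbol": ["ERBB"]},
      {"symbol": "PIK3CA", "alias_symbol": ["PI3K"], "prev_symbol": []},
      {"symbol": "TP53", "alias_symbol": ["P53", "LFS1"], "prev_symbol": []},
      {"symbol": "ALK", "alias_symbol": ["CD246"], "prev_symbol": []},
      {"symbol": "PTEN", "alias_symbol": ["MMAC1", "TEP1"], "prev_symbol": []},
      {"symbol": "NRAS", "alias_symbol": ["N-RAS"], "prev_symbol": []},
      {"symbol": "FLT3", "alias_symbol": ["CD135", "STK1"], "prev_symbol": []},
      {"symbol": "KIT", "alias_symbol": ["CD117", "C-KIT"], "prev_symbol": []},
      {"symbol": "ABL1", "alias_symbol": ["C-ABL"], "prev_symbol": ["ABL"]},
      {"symbol": "MET", "alias_symbol": ["HGFR"], "prev_symbol": []},
      {"symbol": "RET", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "ROS1", "alias_symbol": ["MCF3"], "prev_symbol": ["ROS"]},
      {"symbol": "ERBB3", "alias_symbol": ["HER3"], "prev_symbol": []},
      {"symbol": "ERBB4", "alias_symbol": ["HER4"], "prev_symbol": []},
      {"symbol": "FGFR1", "alias_symbol": [], "prev_symbol": ["FLT2"]},
      {"symbol": "FGFR2", "alias_symbol": ["BEK"], "prev_symbol": ["KGFR"]},
      {"symbol": "FGFR3", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "IDH1", "alias_symbol": ["IDH"], "prev_symbol": []},
      {"symbol": "IDH2", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "JAK2", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "NOTCH1", "alias_symbol": ["TAN1"], "prev_symbol": []},
      {"symbol": "CDKN2A", "alias_symbol": ["P16"], "prev_symbol": ["MTS1"]},
      {"symbol": "CCND1", "alias_symbol": [], "prev_symbol": ["BCL1"]},
      {"symbol": "MYC", "alias_symbol": ["c-Myc"], "prev_symbol": []},
      {"symbol": "AKT1", "alias_symbol": ["PKB"], "prev_symbol": []},
      {"symbol": "MTOR", "alias_symbol": [], "prev_symbol": ["FRAP1"]},
      {"symbol": "STK11", "alias_symbol": ["LKB1"], "prev_symbol": []},
      {"symbol": "SMAD4", "alias_symbol": [], "prev_symbol": ["MADH4"]},
      {"symbol": "APC", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "RB1", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "VHL", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "NF1", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "ATM", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "BRCA1", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "BRCA2", "alias_symbol": ["FANCD1"], "prev_symbol": []},
      {"symbol": "ESR1", "alias_symbol": ["ER"], "prev_symbol": []},
      {"symbol": "AR", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "KDR", "alias_symbol": ["VEGFR2"], "prev_symbol": []},
      {"symbol": "PDGFRA", "alias_symbol": [], "prev_symbol": []},
      {"symbol": "GENE1", "alias_symbol": ["OLDSYM1", "SHAREDALIAS"], "prev_symbol": []},
      {"symbol": "GENE2", "alias_symbol": ["SHAREDALIAS"], "prev_symbol": ["OLDSYM2"]}
    ]
  }
}
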