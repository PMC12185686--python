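[
  {
    "name": "Boc",
    "class": "amino",
    "smirks": "[NX3;!$(N=*):1]C(=O)OC(C)(C)C>>[N:1]",
    "protected_example": "CC(C)(C)OC(=O)NCC(=O)O",
    "deprotected_example": "NCC(=O)O"
  },
  {
    "name": "Fmoc",
    "class": "amino",
    "smirks": "[NX3;!$(N=*):1]C(=O)OCC1c2ccccc2-c2ccccc21>>[N:1]",
    "protected_example": "O=C(NCCC)OCC1c2ccccc2-c2ccccc21",
    "deprotected_example": "CCCN"
  },
  {
    "name": "Cbz",
    "class": "amino",
    "smirks": "[NX3;!$(N=*):1]C(=O)OCc1ccccc1>>[N:1]",
    "protected_example": "O=C(NCC)OCc1ccccc1",
    "deprotected_example": "CCN"
  },
  {
    "name": "tBu-ester",
    "class": "carboxyl",
    "smirks": "[CX3:1](=[OX1:2])([#6:4])[OX2:3]C(C)(C)C>>[C:1](=[O:2])([#6:4])[O:3]",
    "protected_example": "CCC(=O)OC(C)(C)C",
    "deprotected_example": "CCC(=O)O"
  },
  {
    "name": "benzyl-ester",
    "class": "carboxyl",
    "smirks": "[CX3:1](=[OX1:2])([#6:4])[OX2:3]Cc1ccccc1>>[C:1](=[O:2])([#6:4])[O:3]",
    "protected_example": "CCC(=O)OCc1ccccc1",
    "deprotected_example": "CCC(=O)O"
  },
  {
    "name": "tBu-ether",
    "class": "hydroxyl",
    "smirks": "[#6;!$([CX3]=O):1][OX2:2]C(C)(C)C>>[#6:1][O:2]",
    "protected_example": "CCCOC(C)(C)C",
    "deprotected_example": "CCCO"
  },
  {
    "name": "benzoate",
    "class": "hydroxyl",
    "smirks": "[#6;!$([CX3]=O):1][OX2:2]C(=O)c1ccccc1>>[#6:1][O:2]",
    "protected_example": "CCCOC(=O)c1ccccc1",
    "deprotected_example": "CCCO"
  }
]
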