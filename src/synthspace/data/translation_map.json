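{
  "description": "Category translation map: transform-language keyword -> SMARTS. Atom entries are element primitives (aromaticity-neutral, so the perception model decides matches). Functional-group templates are plain SMARTS anchored at their first atom; the transpiler wraps them in recursive $(...) expressions and combines presence with OR, absence with AND of negations. Property modes (hcount, hetcount, fgs) are resolved in code with range enumeration.",
  "atom": {
    "C": "#6",
    "N": "#7",
    "O": "#8",
    "S": "#16",
    "P": "#15",
    "B": "#5",
    "F": "#9",
    "CL": "#17",
    "BR": "#35",
    "I": "#53",
    "SI": "#14",
    "HAL": "#9,#17,#35,#53",
    "ANY": "*"
  },
  "atom_property": {
    "HS": {"mode": "hcount"},
    "HETS": {"mode": "hetcount"},
    "FGS": {"mode": "fgs"},
    "NOT FGS": {"mode": "fgs_absent"},
    "ARYL": {"smarts": "a"},
    "AROM": {"mode": "arom"},
    "RING": {"smarts": "R"},
    "NOT RING": {"smarts": "!R"}
  },
  "functional_group": {
    "KETONE": "[CX3](=[OX1])([#6])[#6]",
    "ALDEHYDE": "[CX3H1]=[OX1]",
    "ESTER": "[CX3](=[OX1])[OX2][#6]",
    "CARBOXYLIC*ACID": "[CX3](=[OX1])[OX2H1]",
    "AMIDE": "[CX3](=[OX1])[NX3]",
    "NITRILE": "[CX2]#[NX1]",
    "NITRO": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "HYDROXYL": "[OX2H1]",
    "ETHER": "[OX2;!R]([#6])[#6]",
    "AMINE": "[NX3;H2,H1;!$([NX3][CX3]=[OX1])]",
    "HALIDE": "[F,Cl,Br,I]",
    "BORONIC*ACID": "[BX3]([OX2H1])[OX2H1]",
    "AZIDE": "[$([NX2]=[NX2+]=[NX1-]),$([NX2]=[NX2]=[NX1])]",
    "ALKENE": "[CX3]=[CX3]",
    "ALKYNE": "[CX2]#[CX2]"
  },
  "bond": {
    "-": "-",
    "=": "=",
    "#": "#",
    "~": "~",
    ":": ":"
  },
  "bond_property": {
    "TRIALKYL": {"mode": "append", "smarts": "@"},
    "RING": {"mode": "append", "smarts": "@"},
    "NOT RING": {"mode": "append", "smarts": "!@"},
    "FUSION": {"mode": "fusion"},
    "DIARYL*FUSION": {"mode": "fusion", "aromatic": true},
    "NOT FUSION": {"mode": "fusion_neg"},
    "NOT DIARYL*FUSION": {"mode": "fusion_neg", "aromatic": true}
  },
  "fusion_atom": "$([x3,x4])",
  "fusion_atom_aromatic": "$([a;x3,x4])"
}
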