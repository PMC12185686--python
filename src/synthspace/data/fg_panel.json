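[
  {"kind": "group", "key": "KETONE", "positives": ["CCC(=O)CC", "CC(=O)c1ccccc1"], "negatives": ["CC(=O)O", "CC=O", "CCOC(C)=O"]},
  {"kind": "group", "key": "ALDEHYDE", "positives": ["CC=O", "O=Cc1ccccc1"], "negatives": ["CC(=O)C", "CC(=O)O"]},
  {"kind": "group", "key": "ESTER", "positives": ["CCOC(C)=O"], "negatives": ["CC(=O)O", "CC(=O)C", "CC(=O)N"]},
  {"kind": "group", "key": "CARBOXYLIC*ACID", "positives": ["CC(=O)O", "OC(=O)c1ccccc1"], "negatives": ["CCOC(C)=O", "CC(=O)C", "CCO"]},
  {"kind": "group", "key": "AMIDE", "positives": ["CC(=O)NC", "NC(=O)c1ccccc1"], "negatives": ["CCNC", "CCOC(C)=O"]},
  {"kind": "group", "key": "NITRILE", "positives": ["CC#N"], "negatives": ["CC#CC", "CCN"]},
  {"kind": "group", "key": "NITRO", "positives": ["CC[N+](=O)[O-]"], "negatives": ["CCN", "CC[N+](C)(C)C"]},
  {"kind": "group", "key": "HYDROXYL", "positives": ["CCO", "OC1CCCC1"], "negatives": ["COC", "CC=O"]},
  {"kind": "group", "key": "ETHER", "positives": ["CCOCC", "COc1ccccc1"], "negatives": ["C1CCOC1", "CCO"]},
  {"kind": "group", "key": "AMINE", "positives": ["CCN", "CCNC"], "negatives": ["CC(=O)NC", "CN(C)C"]},
  {"kind": "group", "key": "HALIDE", "positives": ["CCCl", "Brc1ccccc1"], "negatives": ["CCO", "CC"]},
  {"kind": "group", "key": "BORONIC*ACID", "positives": ["OB(O)c1ccccc1"], "negatives": ["COB(OC)c1ccccc1", "CCB(CC)CC"]},
  {"kind": "group", "key": "AZIDE", "positives": ["CCN=[N+]=[N-]"], "negatives": ["CCN", "CC#N"]},
  {"kind": "group", "key": "ALKENE", "positives": ["CC=CC"], "negatives": ["c1ccccc1", "CC#CC"]},
  {"kind": "group", "key": "ALKYNE", "positives": ["CC#CC"], "negatives": ["CC=CC", "CC#N"]},

  {"kind": "pattern", "key": "HS exact", "pattern": "C[HS:2]", "positives": ["CCC"], "negatives": ["CC", "C(Cl)(Cl)(Cl)Cl"]},
  {"kind": "pattern", "key": "HS more-than", "pattern": "C[HS>1]", "positives": ["CC", "CCC"], "negatives": ["c1ccccc1", "ClC(Cl)(Cl)C(Cl)(Cl)Cl"]},
  {"kind": "pattern", "key": "HS less-than", "pattern": "C[HS<1]", "positives": ["CC(C)(C)C"], "negatives": ["CC"]},
  {"kind": "pattern", "key": "HETS zero", "pattern": "C[HETS:0]", "positives": ["CC"], "negatives": ["CN"]},
  {"kind": "pattern", "key": "HETS exact one", "pattern": "C[HETS:1]", "positives": ["CCO"], "negatives": ["CC", "OCO"]},
  {"kind": "pattern", "key": "HETS more-than", "pattern": "C[HETS>1]", "positives": ["OCO"], "negatives": ["CCO", "CC"]},
  {"kind": "pattern", "key": "FGS presence (OR)", "pattern": "C[FGS:KETONE,ESTER]", "positives": ["CCC(=O)CC", "CCOC(C)=O"], "negatives": ["CC(=O)N", "CCN"]},
  {"kind": "pattern", "key": "FGS absence (AND)", "pattern": "C[NOT FGS:KETONE,ESTER][HS:0]", "positives": ["CC(C)(C)C"], "negatives": ["CCC(=O)CC"]},
  {"kind": "pattern", "key": "ARYL", "pattern": "C[ARYL]", "positives": ["c1ccccc1"], "negatives": ["CC=CC", "C1CCCCC1"]},
  {"kind": "pattern", "key": "RING atom", "pattern": "C[RING]", "positives": ["C1CCC1"], "negatives": ["CCCC"]},
  {"kind": "pattern", "key": "NOT RING atom", "pattern": "C[NOT RING][HS<3]", "positives": ["CCC"], "negatives": ["C1CCC1"]},
  {"kind": "pattern", "key": "atom C", "pattern": "C", "positives": ["CC", "c1ccccc1"], "negatives": ["N", "O=S=O"]},
  {"kind": "pattern", "key": "atom N", "pattern": "N", "positives": ["CCN", "c1ccncc1"], "negatives": ["CCO"]},
  {"kind": "pattern", "key": "atom O", "pattern": "O", "positives": ["CCO"], "negatives": ["CCN"]},
  {"kind": "pattern", "key": "atom S", "pattern": "S", "positives": ["CCS"], "negatives": ["CCO"]},
  {"kind": "pattern", "key": "atom P", "pattern": "P", "positives": ["CP(C)C"], "negatives": ["CCN"]},
  {"kind": "pattern", "key": "atom B", "pattern": "B", "positives": ["OB(O)C"], "negatives": ["CCN"]},
  {"kind": "pattern", "key": "atom F", "pattern": "F", "positives": ["CCF"], "negatives": ["CCCl"]},
  {"kind": "pattern", "key": "atom CL", "pattern": "CL", "positives": ["CCCl"], "negatives": ["CCBr"]},
  {"kind": "pattern", "key": "atom BR", "pattern": "BR", "positives": ["CCBr"], "negatives": ["CCCl"]},
  {"kind": "pattern", "key": "atom I", "pattern": "I", "positives": ["CCI"], "negatives": ["CCBr"]},
  {"kind": "pattern", "key": "atom SI", "pattern": "SI", "positives": ["C[Si](C)(C)C"], "negatives": ["CC(C)(C)C"]},
  {"kind": "pattern", "key": "atom HAL", "pattern": "HAL", "positives": ["CCCl", "CCBr", "CCI", "CCF"], "negatives": ["CCO"]},
  {"kind": "pattern", "key": "atom ANY", "pattern": "ANY", "positives": ["C", "O"], "negatives": []},
  {"kind": "pattern", "key": "single bond", "pattern": "C-C", "positives": ["CC"], "negatives": ["C=C", "c1ccccc1"]},
  {"kind": "pattern", "key": "double bond", "pattern": "C=C", "positives": ["C=C"], "negatives": ["CC", "c1ccccc1"]},
  {"kind": "pattern", "key": "triple bond", "pattern": "C#C", "positives": ["CC#CC"], "negatives": ["CC=CC"]},
  {"kind": "pattern", "key": "any bond", "pattern": "C~N", "positives": ["CCN", "CC#N"], "negatives": ["CCO"]},
  {"kind": "pattern", "key": "aromatic bond", "pattern": "C:C", "positives": ["c1ccccc1"], "negatives": ["CC=CC"]},
  {"kind": "pattern", "key": "TRIALKYL ring bond", "pattern": "C-[TRIALKYL]C", "positives": ["C1CCCCC1"], "negatives": ["CCCC"]},
  {"kind": "pattern", "key": "RING bond", "pattern": "C-[RING]C", "positives": ["C1CCC1"], "negatives": ["CCCC"]},
  {"kind": "pattern", "key": "NOT RING bond", "pattern": "C-[NOT RING]C", "positives": ["CCCC"], "negatives": ["C1CCC1"]},
  {"kind": "pattern", "key": "FUSION bond", "pattern": "C[ARYL]:[FUSION]C[ARYL]", "positives": ["c1ccc2ccccc2c1"], "negatives": ["c1ccccc1", "c1ccc(-c2ccccc2)cc1"]},
  {"kind": "pattern", "key": "DIARYL fusion bond", "pattern": "C[ARYL]:[DIARYL*FUSION]C[ARYL]", "positives": ["c1ccc2ccccc2c1"], "negatives": ["c1ccccc1"]},
  {"kind": "fusion_neg", "key": "NOT FUSION bond", "pattern": "C[ARYL]:[NOT FUSION]C[ARYL]-BR", "positives": ["Brc1ccccc1", "Brc1ccc2ccccc2c1"], "negatives": []}
]
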