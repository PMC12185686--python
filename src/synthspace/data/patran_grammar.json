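{
  "description": "Token table for the PATRAN-style pattern micro-grammar. The tokenizer is table-driven: each segment of a pattern side is matched against these regexes in order, so grammar corrections never touch code. The concrete delimiter conventions below are this package's own fixing of the pattern syntax; the keyword vocabulary (HS, HETS, FGS, TRIALKYL, FUSION, ...) is the transform language's.",
  "conventions": {
    "atom_map": "A circumflex suffix ^n on a reactant atom carries the atom map number; product-side maps are implicit by node order starting at 1.",
    "properties": "Square brackets after an atom or bond: [KEY], [KEY:arg,arg], [NOT KEY:...], [KEY>n], [KEY<n]. A property follows the component it annotates.",
    "branches": "Parentheses open/close side chains, as in SMILES/SMARTS.",
    "rings": "%d digits pair up to close rings, as in SMILES; the closing occurrence creates an edge whose start node succeeds its end node.",
    "reaction": "In transform files, reactant sides are separated by ' + ' and the product side follows ' => '; tokenize_pattern receives a single side."
  },
  "tokens": [
    {"kind": "START_SIDECHAIN", "regex": "\\("},
    {"kind": "END_SIDECHAIN", "regex": "\\)"},
    {"kind": "RING", "regex": "%\\d"},
    {"kind": "FUSION", "regex": "\\[(?:NOT +)?(?:DIARYL\\*)?FUSION\\]"},
    {"kind": "PROPERTY", "regex": "\\[[^\\]]+\\]"},
    {"kind": "BOND", "regex": "[-=#~:]"},
    {"kind": "ATOM", "regex": "(?:CL|BR|SI|HAL|ANY|[CNOSPBFI])(?:\\^\\d+)?"}
  ]
}
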