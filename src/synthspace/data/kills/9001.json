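{
  "transform": 9001,
  "statements": [
    {"index": 0, "smarts": ["[101#7]~[#6]~[F,Cl,Br,I]"], "scope": "ONPATH", "participants": [1], "goto": 3},
    {"index": 1, "smarts": ["[101#7]-[#6]-[#6]-[#8]", "[102#6]-[#6]-c"], "scope": "ONPATH", "participants": [1, 2], "goto": null},
    {"index": 2, "smarts": ["[101#7]-[#6]-[#6]#[#7]"], "scope": "ONPATH", "participants": [1], "goto": null},
    {"index": 3, "smarts": ["[102#6]-[#6]-[F,Cl,Br,I]"], "scope": "ONPATH", "participants": [2], "goto": null}
  ],
  "untranslatable": ["LESS*HINDERED"]
}
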