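{
  "transform": 9003,
  "statements": [
    {"index": 0, "smarts": ["[101#7]-[#7]", "[102#7]-[#7]"], "scope": "OFFPATH", "participants": [1, 2], "goto": null},
    {"index": 1, "smarts": ["[#6X3]=[OX1]"], "scope": "ONPATH", "participants": [3], "goto": null}
  ],
  "untranslatable": []
}
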