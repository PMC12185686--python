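{
  "transform": 9002,
  "statements": [
    {"index": 0, "smarts": ["[#6X3;H1]=[OX1]"], "scope": "ONPATH", "participants": [2], "goto": null}
  ],
  "untranslatable": []
}
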