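# Toy amine arylation: the pattern context atom C^3 double-matches secondary
# amines, so the duplicate policy decides their fate.
TRANSFORM 9004
NAME Toy amine arylation
PATTERN C^3-N^1[HS>0] + C^2[ARYL]-B(-O[HS:1])(-O[HS:1]) => N(-C)-C
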