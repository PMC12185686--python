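# Toy alkene arylation with a symmetric alkene pattern: every 1,2-
# disubstituted alkene double-matches, so the SPACE policy yields no
# products while LIB2020 unifies the matches.
TRANSFORM 9005
NAME Toy alkene arylation
PATTERN C^1[HS:1]=C^2[HS:1] + C^3[ARYL]-BR => C(=C)-C
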