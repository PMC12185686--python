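# Toy amide coupling: amine + carboxylic acid -> amide (water loss).
TRANSFORM 9001
NAME Toy amide coupling
PATTERN N^1[HS>0][HETS:0] + C^2[HS:0](=O^3)-O[HS:1] => N(-C(=O))
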