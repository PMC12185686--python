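# Toy pyrazole condensation: monosubstituted hydrazine + methyl-anchored
# 1,3-diketone -> 1,3,5-trisubstituted pyrazole (ring-forming, two link
# bonds, explicit product aromaticity, double water loss).
TRANSFORM 9003
NAME Toy pyrazole condensation
PATTERN N^1[HS:1]-N^2[HS:2] + C^6[HS:3]-C^3[HS:0](=O)-C^4[HS:2]-C^5[HS:0](=O) => N[AROM]%1-N[AROM]=C[AROM](-C[AROM](=C[AROM]%1))-C
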