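# Toy fused-aryl coupling: the negated fusion-bond property on the C1:C2
# edge splits the rule into two sub-reaction variants.
TRANSFORM 9006
NAME Toy fused-aryl coupling
PATTERN C^1[ARYL]:[NOT FUSION]C^2[ARYL]-BR + C^3[ARYL]-B(-O[HS:1])(-O[HS:1]) => C[AROM]:C[AROM]-C
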