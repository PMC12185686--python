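# Toy biaryl cross-coupling: aryl bromide + arylboronic acid -> biaryl.
TRANSFORM 9002
NAME Toy biaryl coupling
PATTERN C^1[ARYL]-BR + C^2[ARYL]-B(-O[HS:1])(-O[HS:1]) => C(-C)
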