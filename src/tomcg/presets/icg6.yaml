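# Six-step incremental centipede game (same rules as icg4, L=6).
game: icg6
variant: incremental
L: 6
M: 0.5
growth: 2
split: 0.8
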