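# Four-step incremental centipede game: resource 0.5 doubling each step,
# taker receives 80%, pass-through doubles once more and favors Player 1.
game: icg4
variant: incremental
L: 4
M: 0.5
growth: 2
split: 0.8
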