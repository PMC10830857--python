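# Constant-size centipede game template (L=6). The per-step payoff table is
# intentionally left empty: fill `schedule` with six [pi1, pi2] rows and
# `pass_through` with the final division from the constant-sum experiment
# you wish to reproduce (e.g. Fey, McKelvey & Palfrey 1996).
game: ccg6
variant: constant
L: 6
schedule: []
pass_through: []
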