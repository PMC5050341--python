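>G_seed1 synthetic
NGFVTHNC
>G_seed2 synthetic
NGFVTHNC
>G_seed3 synthetic
NGFVSHNC
>G_seed4 synthetic
NGFITHNS
>G_seed5 synthetic
NGYVTHNC
>G_seed6 synthetic penultimate-Gly variant
NGFVTGNC
>G_seed7 synthetic penultimate-Lys variant
NGFVTKNT
>G_seed8 synthetic
DGFVTHNC
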