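>H_seed1 synthetic
IRPVNRLINS
>H_seed2 synthetic
IRPVNRLINS
>H_seed3 synthetic
IRPVNRLLNS
>H_seed4 synthetic
IKPVNRLINS
>H_seed5 synthetic
IRPVNKLINT
>H_seed6 synthetic
VRPVNRLINS
>H_seed7 synthetic
IRPINRLINS
>H_seed8 synthetic
IRPVNRMINS
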