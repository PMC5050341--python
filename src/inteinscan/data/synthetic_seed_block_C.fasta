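>C_seed1 synthetic LAGLIDADG core
KYLAGLIDADGS
>C_seed2 synthetic LAGLIDADG core
KYLAGLIDADGS
>C_seed3 synthetic LAGLIDADG core
KFLAGLIDADGS
>C_seed4 synthetic LAGLIDADG core
KYLAGLVDADGS
>C_seed5 synthetic LAGLIDADG core
RYLAGLIDADGS
>C_seed6 synthetic LAGLIDADG core
KYLAGLIDGDGS
>C_seed7 synthetic LAGLIDADG core
KYLAGFIDADGT
>C_seed8 synthetic LAGLIDADG core
KYLAGLIDADGA
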