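>E_seed1 synthetic LAGLIDADG core
EAYLAGLFDAEG
>E_seed2 synthetic LAGLIDADG core
EAYLAGLFDAEG
>E_seed3 synthetic LAGLIDADG core
EAYLAGLFDADG
>E_seed4 synthetic LAGLIDADG core
DAYLAGLFDAEG
>E_seed5 synthetic LAGLIDADG core
EAYLAGMFDAEG
>E_seed6 synthetic LAGLIDADG core
EAYLSGLFDAEG
>E_seed7 synthetic LAGLIDADG core
EAYLAGLFEAEG
>E_seed8 synthetic LAGLIDADG core
EAFLAGLFDAEG
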